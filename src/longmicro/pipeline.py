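"""End-to-end orchestration: configuration, stage ordering, manifests.

Stages run in dependency order (io -> diversity -> abx -> alpha -> enzyme ->
hmo -> association). A single global seed expands into per-stage seeds via a
stable hash of the stage name, so each stage is independently reproducible;
reruns with an identical configuration are bit-identical (no timestamps
enter any output). Each stage writes TSVs into its own subdirectory of the
output directory and never touches another stage's outputs; the manifest
records per-stage seeds, row counts and output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io import (
    FLOAT_FMT,
    read_homology_hits,
    read_metadata,
    read_stratified_table,
    read_tax_profiles,
    records_to_frame,
)

logger = logging.getLogger("longmicro.pipeline")

STAGES = ("io", "diversity", "abx", "alpha", "enzyme", "hmo", "association")

_DEPENDS = {
    "diversity": ("io",),
    "abx": ("io",),
    "alpha": ("io",),
    "enzyme": ("io",),
    "hmo": ("io",),
    "association": ("io",),
}


class PipelineDependencyError(RuntimeError):
    pass


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    input_dir: str | None = None
    simulate: dict | None = None  # CohortConfig overrides
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        if self.input_dir is None and self.simulate is None:
            raise ValueError("need either input_dir or a simulate block")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def derive_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: first 4 bytes of sha256("<seed>:<stage>") mod 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> int:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
    return len(df)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return (and write) the run manifest."""
    from . import antibiotics, association, diversity, enzymes, hmo, trajectory
    from .simulate import CohortConfig, generate_cohort, generate_homology_hits

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in STAGES if s in config.stages]
    for s in enabled:
        for dep in _DEPENDS.get(s, ()):
            if dep not in enabled:
                raise PipelineDependencyError(
                    f"stage '{s}' requires stage '{dep}', which is disabled"
                )

    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        # hash of the analytical configuration (the output location is
        # incidental and kept out, so reruns elsewhere compare equal)
        "config_hash": hashlib.sha256(
            json.dumps(
                {k: v for k, v in dataclasses.asdict(config).items()
                 if k != "out_dir"},
                sort_keys=True,
            ).encode()
        ).hexdigest(),
        "stage_seeds": {s: derive_seed(config.seed, s) for s in enabled},
        "row_counts": {},
        "outputs": {},
    }
    params = config.params
    written: list[Path] = []

    records = tax = table = hits = None
    if "io" in enabled:
        d = out / "io"
        if config.simulate is not None:
            sim = dict(config.simulate)
            sim.setdefault("seed", derive_seed(config.seed, "io"))
            cc = CohortConfig(**sim)
            records, tax, table, truth = generate_cohort(cc)
            d.mkdir(parents=True, exist_ok=True)
            from .io import write_homology_hits, write_metadata

            write_metadata(records, d / "metadata.tsv")
            tax.to_tsv(d / "taxonomic_profiles.tsv")
            table.to_tsv(d / "functional_profiles.tsv")
            write_homology_hits(generate_homology_hits(cc), d / "homology_hits.tsv")
            truth.to_dir(d / "truth")
        else:
            src = Path(config.input_dir)
            d.mkdir(parents=True, exist_ok=True)
            for f in ("metadata.tsv", "taxonomic_profiles.tsv",
                      "functional_profiles.tsv", "homology_hits.tsv"):
                (d / f).write_bytes((src / f).read_bytes())
        records = read_metadata(d / "metadata.tsv")
        tax = read_tax_profiles(d / "taxonomic_profiles.tsv")
        table = read_stratified_table(d / "functional_profiles.tsv")
        hits = read_homology_hits(d / "homology_hits.tsv")
        manifest["row_counts"]["io"] = len(records)
        written += sorted(d.glob("*.tsv"))

    dm = None
    if "diversity" in enabled:
        d = out / "diversity"
        seed = derive_seed(config.seed, "diversity")
        dm = diversity.bray_curtis_matrix(tax)
        alpha = trajectory.shannon_trajectory(records, tax)
        alpha["dominance"] = [
            diversity.classify_dominance(tax.data.loc[s]) for s in alpha.index
        ]
        n = _write(alpha.reset_index(), d / "alpha_diversity.tsv")
        p = params.get("stability", {})
        stab = diversity.stability_windows(dm, records, seed=seed, **p)
        _write(stab, d / "stability_windows.tsv")
        meta = records_to_frame(records)
        perm = diversity.permanova(
            dm, meta.loc[list(dm.ids), "subject_id"].to_numpy(),
            n_perm=params.get("permanova", {}).get("n_perm", 999),
            seed=seed, term="subject",
        )
        _write(pd.DataFrame([perm.__dict__]), d / "permanova_subject.tsv")
        manifest["row_counts"]["diversity"] = n
        written += sorted(d.glob("*.tsv"))

    pairs = None
    if "abx" in enabled:
        d = out / "abx"
        seed = derive_seed(config.seed, "abx")
        p = params.get("abx", {})
        pairs = antibiotics.consecutive_pairs(
            records,
            max_gap_days=p.get("max_gap_days", 50),
            max_age_days=p.get("max_age_days", 1095),
        )
        pair_df = pd.DataFrame([pr.__dict__ for pr in pairs])
        _write(pair_df, d / "consecutive_pairs.tsv")
        if dm is None:
            dm = diversity.bray_curtis_matrix(tax)
        bifs = [s for s in tax.data.columns if s.startswith("Bifidobacterium")]
        fc = antibiotics.fold_change_table(
            pairs, tax, bifs, n_boot=p.get("n_boot", 1000), seed=seed
        )
        n = _write(fc, d / "species_fold_change.tsv")
        manifest["row_counts"]["abx"] = n
        written += sorted(d.glob("*.tsv"))

    if "alpha" in enabled:
        d = out / "alpha"
        traj = trajectory.shannon_trajectory(records, tax)
        by_id = {r.sample_id: r for r in records}
        fit = trajectory.fit_sigmoid(traj["age_days"], traj["shannon"])
        resid = fit.residuals(traj["age_days"], traj["shannon"])
        covs = params.get("alpha", {}).get(
            "covariates", ["breastfeeding", "delivery_mode", "abx30d"]
        )
        recs = [by_id[s] for s in traj.index]
        assoc = trajectory.residual_mixed_model(resid, recs, covs)
        _write(
            pd.DataFrame(
                [{"d_min": fit.d_min, "d_max": fit.d_max, "k": fit.k,
                  "t_mid": fit.t_mid, "rss": fit.rss, "converged": fit.converged}]
            ),
            d / "sigmoid_fit.tsv",
        )
        n = _write(pd.DataFrame([a.__dict__ for a in assoc]),
                   d / "residual_associations.tsv")
        manifest["row_counts"]["alpha"] = n
        written += sorted(d.glob("*.tsv"))

    if "enzyme" in enabled:
        d = out / "enzyme"
        p = params.get("enzyme", {})
        ages = p.get("ages", (90, 365))
        m3 = enzymes.subject_timepoint_abundance(table, records, ages[0])
        y1 = enzymes.subject_timepoint_abundance(table, records, ages[1])
        ec_cols = [c for c in m3.columns if c[0].isdigit()]  # EC numbers only
        inc, dec = enzymes.consistency_ranking(
            m3[ec_cols], y1[ec_cols], top_k=p.get("top_k", 20)
        )
        _write(inc.assign(direction="increase"), d / "consistency_increases.tsv")
        n = _write(dec.assign(direction="decrease"), d / "consistency_decreases.tsv")
        feats = list(inc["feature_id"]) + list(dec["feature_id"])
        cm = enzymes.contribution_matrix(table, records, feats, ages[0])
        _write(enzymes.contribution_long_table(cm), d / "contributions_t0.tsv")
        manifest["row_counts"]["enzyme"] = n
        written += sorted(d.glob("*.tsv"))

    if "hmo" in enabled:
        d = out / "hmo"
        p = params.get("hmo", {})
        kept = hmo.filter_hits(
            hits,
            min_identity=p.get("min_identity", 50.0),
            min_coverage=p.get("min_coverage", 0.8),
        )
        calls, eligible = hmo.call_presence(
            table, kept, records,
            min_breastfed_samples=p.get("min_breastfed_samples", 50),
        )
        tests = hmo.differential_prevalence(
            calls, eligible, tax, records,
            min_species_abund=p.get("min_species_abund", 1.0),
            alpha=p.get("alpha", 0.001),
        )
        n = _write(hmo.prevalence_frame(tests), d / "prevalence_tests.tsv")
        manifest["row_counts"]["hmo"] = n
        written += sorted(d.glob("*.tsv"))

    if "association" in enabled:
        d = out / "association"
        p = params.get("association", {})
        from .simulate import PATHWAY_CASE, PATHWAY_NULL

        feats = [
            c for c in table.community.columns
            if c in ([PATHWAY_CASE] + PATHWAY_NULL)
        ] or [c for c in table.community.columns if c != "UNMAPPED"]
        res = association.fit_association(
            table.community[feats], records,
            feature_type="pathway",
            cohort=p.get("cohort", "IA"),
            q_threshold=p.get("q_threshold", 0.25),
        )
        n = _write(association.association_frame(res), d / "associations.tsv")
        manifest["row_counts"]["association"] = n
        written += sorted(d.glob("*.tsv"))

    for path in written:
        manifest["outputs"][str(path.relative_to(out))] = _checksum(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
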