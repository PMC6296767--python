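"""Synthetic longitudinal infant-gut cohort generator.

The real cohort this package's analyses were designed around is controlled
access, so the generator emits a cohort with the same *statistical*
structure: monthly stool sampling from about three months of age, per-child
communities dominated in the first year by one of three Bifidobacterium
species or by Proteobacteria, Shannon diversity accruing along a planted
sigmoid with subject random intercepts, antibiotic courses that deplete
susceptible species in the following sample, breastfeeding-coupled
strain-level HMO gene carriage in the *B. longum* fraction, and a planted
case-control shift on one fermentation pathway. Every planted parameter is
recorded in a :class:`TruthTable` keyed by subject/sample/feature ids so
recovery tests can join against it.

Composition model
-----------------
Each sample is a mixture: the subject's dominant taxon holds fraction ``p``
and the remaining ``1 - p`` follows a Dirichlet draw around a subject-
specific base composition over the other panel species (centre effects tilt
the base). ``p`` is solved per sample so the realised Shannon diversity hits
the planted sigmoid-plus-noise target, using the mixture identity

    H = H_binary(p) + p * H_dom + (1 - p) * H_tail,

which is monotone on the right branch; before 365 days ``p`` is floored just
above 0.5 so early dominance (the study's cluster definition) always holds.
This deliberately models compositional and longitudinal structure only, not
ecological interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .diversity import DOMINANCE_TAXA, PROTEOBACTERIA_SPECIES
from .io import (
    HIT_COLUMNS,
    SampleRecord,
    StratifiedTable,
    TaxProfile,
    write_homology_hits,
    write_metadata,
)

CENTRES = ("Finland", "Sweden", "Germany", "Washington", "Georgia", "Colorado")
ABX_CLASSES = ("amoxicillin", "penicillin", "cephalosporins", "macrolide", "other")

#: 30-species panel: (species, genus, phylum)
SPECIES_PANEL = [
    ("Bifidobacterium_longum", "Bifidobacterium", "Actinobacteria"),
    ("Bifidobacterium_breve", "Bifidobacterium", "Actinobacteria"),
    ("Bifidobacterium_bifidum", "Bifidobacterium", "Actinobacteria"),
    ("Bifidobacterium_pseudocatenulatum", "Bifidobacterium", "Actinobacteria"),
    ("Bifidobacterium_adolescentis", "Bifidobacterium", "Actinobacteria"),
    ("Bifidobacterium_dentium", "Bifidobacterium", "Actinobacteria"),
    ("Bifidobacterium_catenulatum", "Bifidobacterium", "Actinobacteria"),
    ("Escherichia_coli", "Escherichia", "Proteobacteria"),
    ("Klebsiella_pneumoniae", "Klebsiella", "Proteobacteria"),
    ("Enterobacter_cloacae", "Enterobacter", "Proteobacteria"),
    ("Bacteroides_fragilis", "Bacteroides", "Bacteroidetes"),
    ("Bacteroides_vulgatus", "Bacteroides", "Bacteroidetes"),
    ("Bacteroides_dorei", "Bacteroides", "Bacteroidetes"),
    ("Alistipes_shahii", "Alistipes", "Bacteroidetes"),
    ("Prevotella_copri", "Prevotella", "Bacteroidetes"),
    ("Faecalibacterium_prausnitzii", "Faecalibacterium", "Firmicutes"),
    ("Roseburia_hominis", "Roseburia", "Firmicutes"),
    ("Ruminococcus_gnavus", "Ruminococcus", "Firmicutes"),
    ("Ruminococcus_bromii", "Ruminococcus", "Firmicutes"),
    ("Eubacterium_rectale", "Eubacterium", "Firmicutes"),
    ("Anaerostipes_hadrus", "Anaerostipes", "Firmicutes"),
    ("Blautia_wexlerae", "Blautia", "Firmicutes"),
    ("Clostridium_neonatale", "Clostridium", "Firmicutes"),
    ("Veillonella_parvula", "Veillonella", "Firmicutes"),
    ("Lactobacillus_rhamnosus", "Lactobacillus", "Firmicutes"),
    ("Streptococcus_thermophilus", "Streptococcus", "Firmicutes"),
    ("Lactococcus_lactis", "Lactococcus", "Firmicutes"),
    ("Enterococcus_faecalis", "Enterococcus", "Firmicutes"),
    ("Akkermansia_muciniphila", "Akkermansia", "Verrucomicrobia"),
    ("Collinsella_aerofaciens", "Collinsella", "Actinobacteria"),
]
SPECIES = [s for s, _, _ in SPECIES_PANEL]
_GENUS = {s: g for s, g, _ in SPECIES_PANEL}
_PHYLUM = {s: p for s, _, p in SPECIES_PANEL}

HMO_GENE_PREFIX = "UniRef90_HMO"
EC_NULL = [
    "2.7.7.7", "3.2.1.23", "6.3.2.6", "1.2.1.12", "4.2.1.2",
    "2.6.1.1", "5.3.1.9", "3.6.1.1", "2.7.1.11", "1.1.1.1",
]
EC_MILK = "1.1.1.27"      # L-lactate dehydrogenase: milk fermentation, declines
EC_FIBRE = "2.2.1.1"      # transketolase: fibre metabolism, rises with solids
PATHWAY_CASE = "PWY4LZ-257"  # fermentation superpathway carrying the case effect
PATHWAY_NULL = [
    "ARGDEG-PWY", "PWY-5676", "P161-PWY", "PWY-7013",
    "PWY-6305", "GLYCOLYSIS", "PWY-5100",
]


def lineage(species: str) -> str:
    g, p = _GENUS[species], _PHYLUM[species]
    return (
        f"k__Bacteria|p__{p}|c__{p}_c|o__{g}ales|f__{g}aceae|g__{g}|s__{species}"
    )


@dataclass
class CohortConfig:
    """Planted parameters of a synthetic cohort; defaults define the default
    study conditions (monthly sampling from day 90, three-year follow-up,
    six centres, breastfeeding duration matching ~73% breastfed at 3 months
    and ~28% at 1 year)."""

    n_subjects: int = 100
    sampling_start_days: int = 90
    sampling_interval_days: int = 30
    max_age_days: int = 1095
    jitter_days: int = 7
    n_centres: int = 6
    dominance_probs: tuple = (0.35, 0.25, 0.20, 0.20)  # over DOMINANCE_TAXA
    breastfeeding_lognorm: tuple = (5.2, 1.2)  # ln-days mean, sd
    solid_food_range: tuple = (30, 140)
    caesarean_prob: float = 0.25
    unknown_breastfeeding_prob: float = 0.02
    t1d_fraction: float = 0.2
    abx_rate: float = 1.0  # expected courses per year
    abx_course_days: int = 7
    abx_depletion_log2fc: dict = field(
        default_factory=lambda: {"Bifidobacterium_bifidum": -2.0}
    )
    abx_log2fc_sd: float = 0.3
    abx_disruption: float = 0.3  # tail-concentration multiplier after a course
    abx_dominance_knockdown: float = 0.65  # dominant-fraction multiplier
    hmo_n_genes: int = 10
    hmo_planted_genes: int = 5
    hmo_carriage_prob_breastfed: float = 0.8
    hmo_carriage_prob_weaned: float = 0.2
    hmo_null_carriage_prob: float = 1.0  # non-contrasted genes are core genes
    hmo_carrier_species: str = "Bifidobacterium_longum"
    sigmoid_params: tuple = (0.8, 2.6, 0.012, 400.0)  # d_min, d_max, k, t_mid
    diversity_noise_sd: float = 0.2
    subject_intercept_sd: float = 0.15
    tail_concentration: float = 8.0
    detection_floor_pct: float = 0.01  # abundances below this report as 0
    centre_effect_sd: float = 0.25
    case_effect: float = 1.0  # log2 shift on PATHWAY_CASE in controls
    reads_lognorm: tuple = (16.1, 0.3)  # ln-reads: ~10M reads
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.sampling_interval_days <= 0:
            raise ValueError("sampling interval must be positive")
        p = np.asarray(self.dominance_probs, dtype=float)
        if len(p) != len(DOMINANCE_TAXA) or (p < 0).any() or (p > 1).any():
            raise ValueError("dominance_probs must be 4 probabilities")
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("dominance_probs must sum to 1")
        for prob in (
            self.hmo_carriage_prob_breastfed,
            self.hmo_carriage_prob_weaned,
            self.hmo_null_carriage_prob,
            self.caesarean_prob,
            self.unknown_breastfeeding_prob,
        ):
            if not 0 <= prob <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 1 <= self.n_centres <= len(CENTRES):
            raise ValueError(f"n_centres must be in [1, {len(CENTRES)}]")
        d_min, d_max, k, t_mid = self.sigmoid_params
        if d_max < d_min or k <= 0:
            raise ValueError("sigmoid needs d_max >= d_min and k > 0")

    @property
    def hmo_genes(self) -> list[str]:
        return [f"{HMO_GENE_PREFIX}{i:04d}" for i in range(self.hmo_n_genes)]


@dataclass
class TruthTable:
    """Planted parameters, keyed by ids for recovery tests."""

    subjects: pd.DataFrame       # dominance, intercept, weaning, solids, outcome
    carriage: pd.DataFrame       # subject x gene flags per feeding state
    abx_events: pd.DataFrame     # realised per-event log2 fold changes
    sigmoid_params: dict         # d_min, d_max, k, t_mid
    case_effect_feature: str
    case_effect_log2: float
    planted_hmo_genes: list[str]

    def to_dir(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(d / "truth_subjects.tsv", sep="\t", index=False)
        self.carriage.to_csv(d / "truth_carriage.tsv", sep="\t", index=False)
        self.abx_events.to_csv(d / "truth_abx_events.tsv", sep="\t", index=False)
        scalars = dict(self.sigmoid_params)
        scalars["case_effect_feature"] = self.case_effect_feature
        scalars["case_effect_log2"] = self.case_effect_log2
        scalars["planted_hmo_genes"] = ";".join(self.planted_hmo_genes)
        pd.Series(scalars).rename_axis("parameter").rename("value").to_csv(
            d / "truth_scalars.tsv", sep="\t"
        )


def _sigmoid(t, d_min, d_max, k, t_mid):
    return d_min + (d_max - d_min) / (1.0 + np.exp(-k * (np.asarray(t) - t_mid)))


def _entropy(rows: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        lg = np.where(rows > 0, np.log(np.where(rows > 0, rows, 1.0)), 0.0)
    return -(rows * lg).sum(axis=-1)


def _solve_dominant_fraction(
    target_h: np.ndarray, h_dom: np.ndarray, h_tail: np.ndarray
) -> np.ndarray:
    """Vectorised bisection for p on the decreasing branch of
    H(p) = H_binary(p) + p*H_dom + (1-p)*H_tail."""

    def h_of(p):
        with np.errstate(divide="ignore", invalid="ignore"):
            hb = -p * np.log(p) - (1 - p) * np.log(1 - p)
        hb = np.nan_to_num(hb, nan=0.0)
        return hb + p * h_dom + (1 - p) * h_tail

    # H is unimodal with maximum at p* = 1 / (1 + exp(h_tail - h_dom));
    # solve on [p*, hi] where H decreases.
    p_star = 1.0 / (1.0 + np.exp(np.clip(h_tail - h_dom, -200, 200)))
    lo = np.maximum(p_star, 1e-4)
    hi = np.full_like(lo, 0.9995)
    target = np.minimum(target_h, h_of(lo))  # clip to the achievable maximum
    for _ in range(50):
        mid = (lo + hi) / 2.0
        too_high = h_of(mid) > target  # diversity still above target: raise p
        lo = np.where(too_high, mid, lo)
        hi = np.where(too_high, hi, mid)
    return (lo + hi) / 2.0


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[SampleRecord], TaxProfile, StratifiedTable, TruthTable]:
    """Generate a cohort; fully reproducible from ``config`` (incl. its seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_species = len(SPECIES)
    sp_index = {s: i for i, s in enumerate(SPECIES)}
    centres = list(CENTRES[: config.n_centres])
    proteo_idx = [sp_index[s] for s in PROTEOBACTERIA_SPECIES]
    d_min, d_max, k_sig, t_mid = config.sigmoid_params

    # centre effects: multiplicative tilt on the tail base composition
    centre_tilt = {
        c: np.exp(rng.normal(0.0, config.centre_effect_sd, size=n_species))
        for c in centres
    }

    # --- subjects ------------------------------------------------------
    subject_ids = [f"S{i:04d}" for i in range(config.n_subjects)]
    n_pairs = config.n_subjects // 2
    pair_of: dict[str, str | None] = {s: None for s in subject_ids}
    outcome_of: dict[str, str] = {s: "control" for s in subject_ids}
    centre_of: dict[str, str] = {}
    order = rng.permutation(config.n_subjects)
    for j in range(n_pairs):
        a, b = subject_ids[order[2 * j]], subject_ids[order[2 * j + 1]]
        pid = f"P{j:03d}"
        pair_of[a] = pair_of[b] = pid
        case_type = "T1D" if rng.random() < config.t1d_fraction else "IA"
        outcome_of[a] = case_type
        centre = centres[j % len(centres)]
        centre_of[a] = centre_of[b] = centre
    for s in subject_ids:  # odd leftover subject
        if s not in centre_of:
            centre_of[s] = centres[int(rng.integers(len(centres)))]

    dom_states = rng.choice(
        len(DOMINANCE_TAXA), size=config.n_subjects, p=config.dominance_probs
    )
    mu_bf, sd_bf = config.breastfeeding_lognorm
    weaned_true = np.maximum(
        30, np.round(np.exp(rng.normal(mu_bf, sd_bf, config.n_subjects)))
    ).astype(int)
    solid_age = rng.integers(
        config.solid_food_range[0], config.solid_food_range[1] + 1,
        size=config.n_subjects,
    )
    caesarean = rng.random(config.n_subjects) < config.caesarean_prob
    unknown_bf = rng.random(config.n_subjects) < config.unknown_breastfeeding_prob
    u_div = rng.normal(0.0, config.subject_intercept_sd, config.n_subjects)
    # pathway subject intercepts (log2 scale), per subject x feature
    pathways = [PATHWAY_CASE] + PATHWAY_NULL
    u_path = rng.normal(0.0, 0.5, size=(config.n_subjects, len(pathways)))
    ec_all = [EC_MILK, EC_FIBRE] + EC_NULL
    u_ec = rng.normal(0.0, 0.3, size=(config.n_subjects, len(ec_all)))

    # HMO carriage flags per subject x gene and feeding state
    genes = config.hmo_genes
    planted = genes[: config.hmo_planted_genes]
    p_bf = np.array(
        [
            config.hmo_carriage_prob_breastfed
            if g in planted else config.hmo_null_carriage_prob
            for g in genes
        ]
    )
    p_wn = np.array(
        [
            config.hmo_carriage_prob_weaned
            if g in planted else config.hmo_null_carriage_prob
            for g in genes
        ]
    )
    carry_bf = rng.random((config.n_subjects, len(genes))) < p_bf
    carry_wn = rng.random((config.n_subjects, len(genes))) < p_wn
    # genes without a planted breastfeeding contrast keep the same strain
    # carriage across weaning (no strain shift), so they are true nulls
    is_null_gene = np.array([g not in planted for g in genes])
    carry_wn[:, is_null_gene] = carry_bf[:, is_null_gene]

    records: list[SampleRecord] = []
    tax_rows, tax_ids = [], []
    hmo_rows, ec_comm_rows, ec_strat_rows, path_rows, unmapped_vals = [], [], [], [], []
    abx_event_rows = []
    subj_truth_rows = []

    for si, subj in enumerate(subject_ids):
        centre = centre_of[subj]
        dom_taxon = DOMINANCE_TAXA[dom_states[si]]
        weaned = int(weaned_true[si])

        # antibiotic courses over the whole follow-up
        span_years = config.max_age_days / 365.0
        n_courses = rng.poisson(config.abx_rate * span_years)
        starts = np.sort(rng.integers(30, config.max_age_days, size=n_courses))
        courses = [
            (int(s), int(s) + config.abx_course_days,
             ABX_CLASSES[int(rng.integers(len(ABX_CLASSES)))])
            for s in starts
        ]

        # collection ages: monthly grid + uniform jitter
        base = np.arange(
            config.sampling_start_days, config.max_age_days + 1,
            config.sampling_interval_days,
        )
        ages = base + rng.integers(
            -config.jitter_days, config.jitter_days + 1, size=len(base)
        )
        ages = np.unique(ages[(ages > 0) & (ages <= config.max_age_days)])
        n_s = len(ages)
        if n_s == 0:
            continue

        # dominant-mass split (phylum states spread over member species)
        if dom_taxon == "Proteobacteria":
            dom_members = proteo_idx
            v = rng.dirichlet([4.0, 2.0, 1.5])
        else:
            dom_members = [sp_index[dom_taxon]]
            v = np.ones(1)
        h_dom_scalar = _entropy(v[None, :])[0]

        # subject tail base over non-dominant species, tilted by centre
        tail_idx = np.array([i for i in range(n_species) if i not in dom_members])
        alpha = 2.0 * centre_tilt[centre][tail_idx]
        w_subj = rng.dirichlet(alpha)

        # per-sample tail draws; antibiotic-affected samples get extra shake
        abx_after = np.zeros(n_s, dtype=bool)
        for start, _, _ in courses:
            hit = np.flatnonzero(ages > start)
            if len(hit) and (hit[0] == 0 or ages[hit[0] - 1] < start):
                j = hit[0]
                if j > 0:
                    abx_after[j] = True
        # tail concentration ramps with age: early communities are sparse
        # and turbulent, mature ones richer and more stable (also gives the
        # upper sigmoid asymptote entropic headroom)
        conc = config.tail_concentration * (0.7 + 1.43 * ages / 365.0)
        conc = np.where(abx_after, conc * config.abx_disruption, conc)
        tails = np.vstack(
            [rng.dirichlet(conc[j] * w_subj) for j in range(n_s)]
        )
        h_tail = _entropy(tails)

        # planted Shannon target and dominant fraction
        target_h = (
            _sigmoid(ages, d_min, d_max, k_sig, t_mid)
            + u_div[si]
            + rng.normal(0.0, config.diversity_noise_sd, n_s)
        )
        target_h = np.maximum(target_h, 0.05)
        p_dom = _solve_dominant_fraction(
            target_h, np.full(n_s, h_dom_scalar), h_tail
        )
        p_dom = np.where(ages < 365, np.maximum(p_dom, 0.505), p_dom)
        # a course also knocks the dominant taxon down in the next sample
        # (perturbed samples are exempt from the dominance floor)
        p_dom = np.where(abx_after, p_dom * config.abx_dominance_knockdown, p_dom)

        fracs = np.zeros((n_s, n_species))
        fracs[:, tail_idx] = (1.0 - p_dom)[:, None] * tails
        for m, mi in enumerate(dom_members):
            fracs[:, mi] = p_dom * v[m]

        # antibiotic depletion override on the sample after a course start:
        # the susceptible species' *relative* abundance is multiplied by
        # 2^(planted + noise); the rest of the community is rescaled.
        for j in np.flatnonzero(abx_after):
            targets = {}
            for sp_name, lfc in config.abx_depletion_log2fc.items():
                i = sp_index[sp_name]
                prev = fracs[j - 1, i]
                if prev <= 0:
                    continue
                realized = lfc + rng.normal(0.0, config.abx_log2fc_sd)
                # cap inside the available headroom so fractions stay valid
                new = min(prev * 2.0 ** realized, prev + 0.9 * (1.0 - prev))
                targets[i] = new
                abx_event_rows.append(
                    {
                        "subject_id": subj,
                        "sample_before": f"{subj}_T{j - 1:02d}",
                        "sample_after": f"{subj}_T{j:02d}",
                        "species": sp_name,
                        "planted_log2fc": lfc,
                        "realized_log2fc": float(np.log2(new / prev)),
                    }
                )
            if targets:
                others = [i for i in range(n_species) if i not in targets]
                remaining = 1.0 - sum(targets.values())
                cur = fracs[j, others].sum()
                if cur > 0:
                    fracs[j, others] *= remaining / cur
                for i, val in targets.items():
                    fracs[j, i] = val

        # profiler detection floor: sub-threshold species report as zero,
        # like real marker-based profiles (no arbitrarily small fractions)
        fracs[fracs < config.detection_floor_pct / 100.0] = 0.0
        fracs /= fracs.sum(axis=1, keepdims=True)

        sample_ids = [f"{subj}_T{j:02d}" for j in range(n_s)]
        blon = fracs[:, sp_index[config.hmo_carrier_species]]

        for j, age in enumerate(ages):
            bf_now = age < weaned
            records.append(
                SampleRecord(
                    sample_id=sample_ids[j],
                    subject_id=subj,
                    age_days=int(age),
                    centre=centre,
                    breastfeeding=None if unknown_bf[si] else bool(bf_now),
                    weaned_age_days=None if unknown_bf[si] else weaned,
                    solid_food_age_days=int(solid_age[si]),
                    antibiotic_courses=courses,
                    delivery_mode="caesarean" if caesarean[si] else "vaginal",
                    outcome=outcome_of[subj],
                    pair_id=pair_of[subj],
                    reads=int(
                        np.exp(rng.normal(*config.reads_lognorm))
                    ),
                )
            )
            tax_ids.append(sample_ids[j])
        tax_rows.append(100.0 * fracs)

        # HMO gene CPMs: carriers scale with B. longum; non-carriers stay
        # below the presence threshold.
        bf_state = ages < weaned
        flags = np.where(
            bf_state[:, None], carry_bf[si][None, :], carry_wn[si][None, :]
        )
        base_cpm = np.exp(rng.normal(np.log(2000.0), 0.6, size=(n_s, len(genes))))
        bg = rng.random((n_s, len(genes))) < 0.1
        noise_cpm = rng.uniform(0.0, 0.5, size=(n_s, len(genes))) * bg
        hmo = np.where(flags, base_cpm * blon[:, None], noise_cpm)
        hmo_rows.append(hmo)

        # EC enzymes: community totals with planted milk/fibre trends
        ln = rng.normal(0.0, 0.3, size=(n_s, len(ec_all)))
        bifido_frac = fracs[
            :, [i for i, s in enumerate(SPECIES) if _GENUS[s] == "Bifidobacterium"]
        ].sum(axis=1)
        milk_factor = 1.0 / (1.0 + np.exp((ages - weaned) / 45.0)) + 0.1
        fibre_factor = 0.15 + 1.0 / (1.0 + np.exp(-(ages - solid_age[si] - 60) / 45.0))
        ec_comm = np.empty((n_s, len(ec_all)))
        ec_comm[:, 0] = 3000.0 * (0.2 + 0.8 * bifido_frac) * milk_factor
        ec_comm[:, 1] = 2500.0 * fibre_factor
        ec_comm[:, 2:] = 800.0
        ec_comm *= np.exp(u_ec[si][None, :] + ln)
        ec_comm_rows.append(ec_comm)
        ec_strat_rows.append(fracs)  # species shares derive from composition

        # pathways (community-only), log2 scale with planted case effect
        age_trend = 0.6 * ages / 365.0
        lp = (
            9.0
            + age_trend[:, None]
            + u_path[si][None, :]
            + rng.normal(0.0, 0.5, size=(n_s, len(pathways)))
        )
        if outcome_of[subj] == "control":
            lp[:, 0] += config.case_effect
        path_rows.append(2.0 ** lp)
        unmapped_vals.append(np.exp(rng.normal(np.log(3.0e5), 0.2, size=n_s)))

        subj_truth_rows.append(
            {
                "subject_id": subj,
                "dominance_state": dom_taxon,
                "diversity_intercept": float(u_div[si]),
                "weaned_age_days_true": weaned,
                "solid_food_age_days": int(solid_age[si]),
                "breastfeeding_known": not bool(unknown_bf[si]),
                "centre": centre,
                "outcome": outcome_of[subj],
                "pair_id": pair_of[subj] or "",
            }
        )

    # --- assemble tables ----------------------------------------------
    tax_data = pd.DataFrame(
        np.vstack(tax_rows), index=pd.Index(tax_ids, name="sample_id"),
        columns=SPECIES,
    )
    tax = TaxProfile(tax_data, {s: lineage(s) for s in SPECIES})
    tax.validate()

    carrier = config.hmo_carrier_species
    hmo_mat = np.vstack(hmo_rows)
    ec_comm_mat = np.vstack(ec_comm_rows)
    comp = np.vstack(ec_strat_rows)

    # stratify ECs over contributing species; leftovers go to UNCLASSIFIED
    bif_mask = np.array([_GENUS[s] == "Bifidobacterium" for s in SPECIES], float)
    lactic = {"Streptococcus_thermophilus", "Lactococcus_lactis",
              "Lactobacillus_rhamnosus"}
    milk_w = bif_mask + np.array([s in lactic for s in SPECIES], float)
    fibre_w = np.array(
        [_PHYLUM[s] in ("Bacteroidetes", "Firmicutes") for s in SPECIES], float
    )
    flat_w = np.ones(len(SPECIES))
    ec_weights = [milk_w, fibre_w] + [flat_w] * len(EC_NULL)

    community: dict[str, np.ndarray] = {}
    stratified: dict[tuple[str, str], np.ndarray] = {}
    community["UNMAPPED"] = np.concatenate(unmapped_vals)
    for gi, g in enumerate(genes):
        vals = hmo_mat[:, gi]
        community[g] = vals
        stratified[(g, carrier)] = vals
    for fi, f in enumerate(ec_all):
        total = ec_comm_mat[:, fi]
        w = comp * ec_weights[fi][None, :]
        wsum = w.sum(axis=1, keepdims=True)
        shares = np.divide(w, wsum, out=np.zeros_like(w), where=wsum > 0)
        attributed = 0.85 * total[:, None] * shares
        community[f] = total
        keep = np.flatnonzero(ec_weights[fi] > 0)
        for i in keep:
            stratified[(f, SPECIES[i])] = attributed[:, i]
        stratified[(f, "UNCLASSIFIED")] = total - attributed.sum(axis=1)
    path_mat = np.vstack(path_rows)
    for pi, pw in enumerate(pathways):
        community[pw] = path_mat[:, pi]

    idx = pd.Index(tax_ids, name="sample_id")
    comm_df = pd.DataFrame(community, index=idx)
    strat_df = pd.DataFrame(stratified, index=idx)
    strat_df.columns = pd.MultiIndex.from_tuples(
        strat_df.columns, names=["feature", "species"]
    )
    tokens = {s: f"g__{_GENUS[s]}.s__{s}" for s in SPECIES}
    tokens["UNCLASSIFIED"] = "unclassified"
    table = StratifiedTable(comm_df, strat_df, tokens)
    table.validate()

    truth = TruthTable(
        subjects=pd.DataFrame(subj_truth_rows),
        carriage=pd.DataFrame(
            [
                {
                    "subject_id": subject_ids[si],
                    "gene_family_id": g,
                    "carries_breastfed": bool(carry_bf[si, gi]),
                    "carries_weaned": bool(carry_wn[si, gi]),
                }
                for si in range(config.n_subjects)
                for gi, g in enumerate(genes)
            ]
        ),
        abx_events=pd.DataFrame(
            abx_event_rows,
            columns=["subject_id", "sample_before", "sample_after", "species",
                     "planted_log2fc", "realized_log2fc"],
        ),
        sigmoid_params={"d_min": d_min, "d_max": d_max, "k": k_sig, "t_mid": t_mid},
        case_effect_feature=PATHWAY_CASE,
        case_effect_log2=config.case_effect,
        planted_hmo_genes=planted,
    )
    return records, tax, table, truth


def generate_homology_hits(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Synthetic translated-search hit table for the HMO gene panel.

    One passing hit per gene for the carrier species, a few passing
    cross-species homologues (no quantification data, so never called
    present), decoys failing the identity or coverage filters, and one
    duplicate hit at lower identity to exercise deduplication.
    """
    rng = np.random.default_rng(config.seed + 7919 if seed is None else seed)
    rows = []

    def hit(query, fam, token, ident, cov_q, cov_s):
        qlen = int(rng.integers(300, 1200))
        length = int(round(cov_q * qlen))
        slen = int(round(length / cov_s)) if cov_s > 0 else qlen * 2
        rows.append(
            {
                "qseqid": query,
                "sseqid": f"{fam}|{token}",
                "pident": round(ident, 2),
                "length": length,
                "mismatch": int(length * (100 - ident) / 100),
                "gapopen": int(rng.integers(0, 5)),
                "qstart": 1, "qend": length, "sstart": 1, "send": length,
                "evalue": 1e-50, "bitscore": round(ident * 5, 1),
                "qlen": qlen, "slen": slen,
            }
        )

    carrier = config.hmo_carrier_species
    token = f"g__{_GENUS[carrier]}.s__{carrier}"
    for i, fam in enumerate(config.hmo_genes):
        q = f"Blon_{2331 + 2 * i}"
        hit(q, fam, token, rng.uniform(55, 95), rng.uniform(0.85, 1.0),
            rng.uniform(0.85, 1.0))
    # duplicate at lower identity for the first gene
    hit("Blon_2331", config.hmo_genes[0], token, 52.0, 0.9, 0.9)
    # passing cross-species homologues without quantification
    ent = "Enterococcus_faecalis"
    for fam in config.hmo_genes[:3]:
        hit("Blon_2349", fam, f"g__{_GENUS[ent]}.s__{ent}", rng.uniform(51, 70),
            0.9, 0.9)
    # decoys: identity or coverage failures
    hit("Blon_2353", "UniRef90_DECOY01", token, 35.0, 0.9, 0.9)
    hit("Blon_2355", "UniRef90_DECOY02", token, 80.0, 0.5, 0.9)
    hit("Blon_2357", "UniRef90_DECOY03", token, 80.0, 0.9, 0.4)
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


FIXTURE_SIZES = {
    "tiny": {"n_subjects": 6, "max_age_days": 360},
    "small": {"n_subjects": 100, "max_age_days": 1095},
}


def emit_fixture(size: str, out_dir, seed: int = 0) -> Path:
    """Write a complete TSV fixture (profiles, metadata, hits, truth).

    ``tiny`` is 6 subjects with at most 10 samples each; ``small`` is the
    default 100-subject cohort. Regeneration with the same seed is
    byte-identical.
    """
    if size not in FIXTURE_SIZES:
        raise ValueError(f"size must be one of {sorted(FIXTURE_SIZES)}")
    config = replace(CohortConfig(), **FIXTURE_SIZES[size], seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, tax, table, truth = generate_cohort(config)
    write_metadata(records, out / "metadata.tsv")
    tax.to_tsv(out / "taxonomic_profiles.tsv")
    table.to_tsv(out / "functional_profiles.tsv")
    write_homology_hits(generate_homology_hits(config), out / "homology_hits.tsv")
    truth.to_dir(out / "truth")
    return out
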