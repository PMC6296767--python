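"""Readers, writers and validation for the tabular formats the pipeline consumes.

Four inputs are supported:

* species-level taxonomic relative-abundance tables (MetaPhlAn2 merged-table
  TSV dialect: pipe-delimited taxonomy strings in column 1, one column per
  sample, values on the 0-100 percent scale),
* species-stratified gene-family / EC / pathway abundance tables (HUMAnN2 TSV
  dialect: row keys ``feature`` or ``feature|g__Genus.s__Species``, values in
  copies per million),
* per-sample metadata TSV (ages already expressed as integer days),
* tabular homology hits (BLAST outfmt-6 columns plus query and subject
  lengths, so mutual coverage can be computed).

Abundances are kept on the percent scale internally; operations needing
fractions divide by 100 at point of use. Dates never appear: all timing is
integer age in days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("longmicro.io")

#: fixed float formatting used by every writer (round-trip stable, and
#: precise enough that per-sample sum and additivity invariants survive a
#: write/read cycle)
FLOAT_FMT = "%.10g"
#: tolerance on per-sample percent sums and stratified/community additivity
SUM_TOL = 1e-6

SPECIES_PREFIX = "s__"
UNCLASSIFIED = "UNCLASSIFIED"
_SPECIAL_COMMUNITY_ROWS = {"UNMAPPED", "UNINTEGRATED"}

METADATA_COLUMNS = [
    "sample_id",
    "subject_id",
    "age_days",
    "centre",
    "breastfeeding",
    "weaned_age_days",
    "solid_food_age_days",
    "antibiotic_courses",
    "delivery_mode",
    "outcome",
    "pair_id",
    "reads",
]


class FormatError(ValueError):
    """Malformed input file (bad header, bad row key, missing columns)."""


class ValidationError(ValueError):
    """Well-formed file whose values violate an invariant."""


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------


@dataclass
class SampleRecord:
    """Metadata for one stool sample.

    ``breastfeeding`` is the status *at collection* (ongoing); ``None`` marks
    subjects with unknown breastfeeding information, which are flagged here
    and excluded by downstream stages rather than dropped at I/O.
    ``antibiotic_courses`` lists every recorded course for the subject as
    ``(start_day, end_day, class)`` in age-days.
    """

    sample_id: str
    subject_id: str
    age_days: int
    centre: str
    breastfeeding: bool | None
    weaned_age_days: int | None
    antibiotic_courses: list[tuple[int, int, str]]
    delivery_mode: str
    outcome: str
    pair_id: str | None
    reads: int
    solid_food_age_days: int | None = None

    def __post_init__(self) -> None:
        if self.age_days < 0:
            raise ValidationError(f"{self.sample_id}: age_days must be >= 0")
        if not self.subject_id:
            raise ValidationError(f"{self.sample_id}: sample without subject")
        for start, end, _ in self.antibiotic_courses:
            if start > end:
                raise ValidationError(
                    f"{self.sample_id}: antibiotic interval start {start} > end {end}"
                )

    @property
    def breastfeeding_known(self) -> bool:
        return self.breastfeeding is not None

    def antibiotics_within(self, lookback_days: int = 30) -> bool:
        """True if any course overlaps the ``lookback_days`` before collection."""
        lo = self.age_days - lookback_days
        return any(s <= self.age_days and e >= lo for s, e, _ in self.antibiotic_courses)

    @property
    def solid_food(self) -> bool:
        return (
            self.solid_food_age_days is not None
            and self.age_days >= self.solid_food_age_days
        )


def _parse_bool(token: str) -> bool | None:
    t = token.strip().lower()
    if t in {"yes", "true", "1"}:
        return True
    if t in {"no", "false", "0"}:
        return False
    if t in {"", "unknown", "na", "nan", "?"}:
        return None
    raise FormatError(f"unparseable breastfeeding value {token!r}")


def _parse_optional_int(token) -> int | None:
    if token is None:
        return None
    t = str(token).strip()
    if t in {"", "na", "NA", "nan", "NaN"}:
        return None
    return int(float(t))


def _parse_courses(token) -> list[tuple[int, int, str]]:
    t = "" if token is None else str(token).strip()
    if t in {"", "na", "NA", "nan"}:
        return []
    out = []
    for chunk in t.split(";"):
        parts = chunk.split(":")
        if len(parts) != 3:
            raise FormatError(f"bad antibiotic course {chunk!r} (want start:end:class)")
        out.append((int(parts[0]), int(parts[1]), parts[2]))
    return out


def read_metadata(path) -> list[SampleRecord]:
    """Read a per-sample metadata TSV into a list of :class:`SampleRecord`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns and c != "solid_food_age_days"]
    if missing:
        raise FormatError(f"metadata missing columns: {missing}")
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        d = row._asdict()
        sid = d["sample_id"].strip()
        if sid in seen:
            raise ValidationError(f"duplicate sample_id {sid!r}")
        seen.add(sid)
        records.append(
            SampleRecord(
                sample_id=sid,
                subject_id=d["subject_id"].strip(),
                age_days=int(float(d["age_days"])),
                centre=d["centre"],
                breastfeeding=_parse_bool(d["breastfeeding"]),
                weaned_age_days=_parse_optional_int(d["weaned_age_days"]),
                solid_food_age_days=_parse_optional_int(d.get("solid_food_age_days")),
                antibiotic_courses=_parse_courses(d["antibiotic_courses"]),
                delivery_mode=d["delivery_mode"],
                outcome=d["outcome"],
                pair_id=d["pair_id"].strip() or None,
                reads=int(float(d["reads"])),
            )
        )
    return records


def write_metadata(records: list[SampleRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "subject_id": r.subject_id,
                "age_days": r.age_days,
                "centre": r.centre,
                "breastfeeding": {True: "yes", False: "no", None: "unknown"}[r.breastfeeding],
                "weaned_age_days": "" if r.weaned_age_days is None else r.weaned_age_days,
                "solid_food_age_days": ""
                if r.solid_food_age_days is None
                else r.solid_food_age_days,
                "antibiotic_courses": ";".join(
                    f"{s}:{e}:{c}" for s, e, c in r.antibiotic_courses
                ),
                "delivery_mode": r.delivery_mode,
                "outcome": r.outcome,
                "pair_id": r.pair_id or "",
                "reads": r.reads,
            }
        )
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def records_to_frame(records: list[SampleRecord]) -> pd.DataFrame:
    """Flatten records into a sample-indexed frame with derived covariates.

    Derived columns: ``weaned`` (collection age at or past the recorded
    weaning age), ``solid_food``, ``abx30d`` (an antibiotic course overlapping
    the previous 30 days) and ``log10_reads``.
    """
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "subject_id": r.subject_id,
                "age_days": r.age_days,
                "centre": r.centre,
                "breastfeeding": r.breastfeeding,
                "breastfeeding_known": r.breastfeeding_known,
                "weaned": (
                    r.weaned_age_days is not None and r.age_days >= r.weaned_age_days
                ),
                "solid_food": r.solid_food,
                "abx30d": r.antibiotics_within(30),
                "delivery_mode": r.delivery_mode,
                "outcome": r.outcome,
                "pair_id": r.pair_id,
                "reads": r.reads,
                "log10_reads": np.log10(max(r.reads, 1)),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# taxonomic profiles
# ---------------------------------------------------------------------------


def species_from_clade(clade: str) -> str | None:
    """Terminal-rank species name of a pipe-delimited taxonomy string.

    Returns ``None`` when the terminal clade is not species-level (genus rows,
    strain rows, ...).
    """
    terminal = clade.split("|")[-1]
    if terminal.startswith(SPECIES_PREFIX):
        return terminal[len(SPECIES_PREFIX):]
    return None


@dataclass
class TaxProfile:
    """Sample x species relative-abundance matrix on the percent scale.

    ``lineages`` maps each species back to its full taxonomy string so tables
    round-trip through :meth:`to_tsv` unchanged.
    """

    data: pd.DataFrame
    lineages: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if (self.data.values < 0).any():
            raise ValidationError("negative abundance in taxonomic profile")
        sums = self.data.sum(axis=1)
        bad = sums[sums > 100 + SUM_TOL]
        if len(bad):
            raise ValidationError(
                f"per-sample species sums exceed 100: {bad.index.tolist()[:5]}"
            )
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate sample ids in taxonomic profile")

    def fractions(self) -> pd.DataFrame:
        """Abundances on the 0-1 fraction scale."""
        return self.data / 100.0

    @classmethod
    def from_tsv(cls, path) -> "TaxProfile":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.shape[1] < 1:
            raise FormatError("taxonomic table must have at least one sample column")
        if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
            raise FormatError("non-numeric abundance column in taxonomic table")
        keep, species, lineages = [], [], {}
        for clade in df.index:
            sp = species_from_clade(str(clade))
            if sp is not None:
                keep.append(clade)
                species.append(sp)
                lineages[sp] = str(clade)
        out = df.loc[keep].T
        out.columns = species
        out.index.name = "sample_id"
        prof = cls(out.astype(float), lineages)
        prof.validate()
        return prof

    def to_tsv(self, path) -> None:
        df = self.data.T.copy()
        df.index = [self.lineages.get(sp, f"{SPECIES_PREFIX}{sp}") for sp in df.index]
        df.index.name = "clade_name"
        df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_tax_profiles(path) -> TaxProfile:
    """Read a merged MetaPhlAn2-style table, keeping species-level rows only."""
    return TaxProfile.from_tsv(path)


# ---------------------------------------------------------------------------
# stratified functional tables
# ---------------------------------------------------------------------------


def _parse_species_token(token: str) -> str:
    if token.lower() == "unclassified":
        return UNCLASSIFIED
    if ".s__" in token:
        return token.split(".s__", 1)[1]
    if token.startswith(SPECIES_PREFIX):
        return token[len(SPECIES_PREFIX):]
    return token


@dataclass
class StratifiedTable:
    """HUMAnN2-style feature abundances in CPM.

    ``community`` holds community-total rows (samples x features);
    ``stratified`` holds per-species attributions (samples x (feature,
    species) MultiIndex). ``tokens`` remembers the original file token of each
    species so tables round-trip.
    """

    community: pd.DataFrame
    stratified: pd.DataFrame
    tokens: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if (self.community.values < 0).any() or (self.stratified.values < 0).any():
            raise ValidationError("negative abundance in stratified table")

    def check_additivity(self, rtol: float = SUM_TOL) -> list[str]:
        """Warn about features whose stratified rows do not sum to the total.

        Returns the offending feature ids; mismatches are logged, not raised
        (HUMAnN2 subsets can legitimately omit stratified rows).
        """
        bad = []
        if self.stratified.empty:
            return bad
        strat_sum = self.stratified.T.groupby(level=0).sum().T
        common = [f for f in strat_sum.columns if f in self.community.columns]
        for f in common:
            total = self.community[f].to_numpy()
            s = strat_sum[f].to_numpy()
            scale = np.maximum(np.abs(total), 1.0)
            if np.any(np.abs(s - total) > rtol * scale):
                bad.append(f)
                logger.warning(
                    "feature %s: stratified rows do not sum to community total", f
                )
        return bad

    def community_feature(self, feature: str) -> pd.Series:
        return self.community[feature]

    @classmethod
    def from_tsv(cls, path) -> "StratifiedTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.shape[1] < 1:
            raise FormatError("stratified table must have at least one sample column")
        comm_keys, comm_feats = [], []
        strat_keys, strat_cols = [], []
        tokens: dict[str, str] = {}
        for key in df.index:
            key = str(key)
            if "|" in key:
                feat, rest = key.split("|", 1)
                if "|" in rest:
                    raise FormatError(f"row key {key!r} has more than one '|' delimiter")
                sp = _parse_species_token(rest)
                tokens[sp] = rest
                strat_keys.append(key)
                strat_cols.append((feat, sp))
            else:
                comm_keys.append(key)
                comm_feats.append(key)
        community = df.loc[comm_keys].T.astype(float)
        community.columns = comm_feats
        community.index.name = "sample_id"
        stratified = df.loc[strat_keys].T.astype(float)
        stratified.columns = pd.MultiIndex.from_tuples(
            strat_cols, names=["feature", "species"]
        ) if strat_cols else pd.MultiIndex.from_arrays([[], []], names=["feature", "species"])
        stratified.index.name = "sample_id"
        table = cls(community, stratified, tokens)
        table.validate()
        table.check_additivity()
        return table

    def to_tsv(self, path) -> None:
        strat_by_feat: dict[str, list[tuple[str, str]]] = {}
        for feat, sp in self.stratified.columns:
            strat_by_feat.setdefault(feat, []).append((feat, sp))
        rows, keys = [], []
        for feat in self.community.columns:
            keys.append(feat)
            rows.append(self.community[feat])
            for feat_sp in strat_by_feat.pop(feat, []):
                keys.append(f"{feat}|{self.tokens.get(feat_sp[1], feat_sp[1])}")
                rows.append(self.stratified[feat_sp])
        for feat, cols in strat_by_feat.items():  # stratified-only features
            for feat_sp in cols:
                keys.append(f"{feat}|{self.tokens.get(feat_sp[1], feat_sp[1])}")
                rows.append(self.stratified[feat_sp])
        out = pd.DataFrame(rows, index=keys)
        out.index.name = "# Gene Family"
        out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_stratified_table(path) -> StratifiedTable:
    """Read a HUMAnN2-style gene-family/EC/pathway table (CPM)."""
    return StratifiedTable.from_tsv(path)


# ---------------------------------------------------------------------------
# homology hits
# ---------------------------------------------------------------------------


@dataclass
class HomologyHit:
    """One tabular alignment hit with mutual-coverage fractions."""

    query_id: str
    gene_family_id: str
    carrier_species: str
    pct_identity: float
    coverage_query: float
    coverage_subject: float

    def __post_init__(self) -> None:
        if not 0 <= self.pct_identity <= 100:
            raise ValidationError(f"identity {self.pct_identity} outside [0, 100]")
        if not (0 <= self.coverage_query <= 1 and 0 <= self.coverage_subject <= 1):
            raise ValidationError("coverage outside [0, 1]")


#: outfmt-6 columns followed by the two length columns needed for coverage
HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qlen", "slen",
]


def read_homology_hits(path) -> list[HomologyHit]:
    """Read 12-column tabular alignment output extended with qlen and slen.

    The subject id must be ``<gene_family>|<species token>`` (pangenome-style
    headers). Coverage on each side is alignment length over the full
    sequence length, capped at 1; both sides must later pass the mutual
    coverage filter.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < len(HIT_COLUMNS):
        raise FormatError(
            "homology hits need 14 columns (outfmt 6 plus qlen and slen); "
            f"got {df.shape[1]} - re-run the search with qlen/slen appended"
        )
    df = df.iloc[:, : len(HIT_COLUMNS)]
    df.columns = HIT_COLUMNS
    hits = []
    for row in df.itertuples(index=False):
        sseqid = str(row.sseqid)
        if "|" not in sseqid:
            raise FormatError(
                f"subject id {sseqid!r} lacks the '<family>|<species>' form"
            )
        fam, token = sseqid.split("|", 1)
        hits.append(
            HomologyHit(
                query_id=str(row.qseqid),
                gene_family_id=fam,
                carrier_species=_parse_species_token(token),
                pct_identity=float(row.pident),
                coverage_query=min(1.0, float(row.length) / float(row.qlen)),
                coverage_subject=min(1.0, float(row.length) / float(row.slen)),
            )
        )
    return hits


def write_homology_hits(rows: pd.DataFrame, path) -> None:
    """Write a 14-column hits table (no header, outfmt-6 convention)."""
    rows[HIT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# directory validation (CLI `longmicro validate`)
# ---------------------------------------------------------------------------

STANDARD_FILES = {
    "metadata": ("metadata.tsv", read_metadata),
    "taxa": ("taxonomic_profiles.tsv", read_tax_profiles),
    "functional": ("functional_profiles.tsv", read_stratified_table),
    "hits": ("homology_hits.tsv", read_homology_hits),
}


def validate_directory(directory) -> dict[str, str]:
    """Run every reader over the standard file layout; return issues by file."""
    from pathlib import Path

    issues: dict[str, str] = {}
    d = Path(directory)
    for name, (fname, reader) in STANDARD_FILES.items():
        p = d / fname
        if not p.exists():
            issues[name] = f"missing file {fname}"
            continue
        try:
            reader(p)
        except (FormatError, ValidationError, ValueError) as exc:
            issues[name] = str(exc)
    return issues
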