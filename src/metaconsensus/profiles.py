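"""Reading, filtering, and cross-classifier harmonization of taxonomic profiles.

Two profile dialects are supported: merged marker-gene tables (one row per
rank-prefixed lineage, one column per sample, MetaPhlAn style) and per-sample
k-mer abundance-reestimation reports (one file per sample with taxon name,
taxonomy ID, read counts and fraction columns, Bracken style).  Profiles from
different classifiers are matched taxon-by-taxon — by NCBI taxonomy ID when
both sides carry one, otherwise by a normalized taxon name — to produce
overlap and shared-abundance accounting.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "TaxonProfile",
    "EvidenceCounts",
    "DatabaseIndex",
    "TaxonAlignment",
    "OverlapSummary",
    "normalize_taxon_name",
    "read_metaphlan_profile",
    "read_bracken_report",
    "read_profile_tsv",
    "filter_low_evidence",
    "align_taxa",
    "overlap_summary",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_PREFIX_TO_RANK = {
    "k": "kingdom",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
    # terminal strain-level rows ("t__") are never requested but must parse
    "t": "strain",
}

# MetaPhlAn genome-bin identifiers (species/genus/family-level genome bins)
# lack an NCBI taxonomy mapping and are excluded from cross-classifier
# matching by default.
_GENOME_BIN_RE = re.compile(r"(?:^|_)(?:SGB|GGB|FGB|CFGB)\d+", re.IGNORECASE)

_LINEAGE_COMPONENT_RE = re.compile(r"^([kpcofgst])__(.*)$")


def _check_level(level: str) -> str:
    level = level.lower()
    if level not in RANKS:
        raise ValueError(f"unknown taxonomic level {level!r}; expected one of {RANKS}")
    return level


def normalize_taxon_name(name: str) -> str:
    """Canonical form used for cross-classifier taxon matching.

    Lowercases, strips a leading rank prefix (``s__`` etc.), and collapses
    runs of whitespace/underscores to single spaces.
    """
    name = name.strip().lower()
    name = re.sub(r"^[kpcofgst]__", "", name)
    name = re.sub(r"[\s_]+", " ", name)
    return name.strip()


def is_genome_bin(name: str) -> bool:
    """True for metagenome-assembled genome-bin labels (SGB/GGB/FGB ids)."""
    return bool(_GENOME_BIN_RE.search(name))


@dataclass
class TaxonProfile:
    """Relative-abundance matrix (taxa x samples) from one classifier.

    ``data`` holds fractions in [0, 1]; rows are taxon names, columns sample
    identifiers.  ``taxids`` optionally maps taxon names to NCBI taxonomy
    IDs, ``lineages`` to full rank-prefixed lineage strings.
    """

    classifier_label: str
    level: str
    data: pd.DataFrame
    taxids: dict[str, int] = field(default_factory=dict)
    lineages: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.level = _check_level(self.level)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxa in profile: {dups}")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers in profile")
        values = self.data.to_numpy(dtype=float)
        if values.size and np.nanmin(values) < 0:
            raise ValueError("negative relative abundances")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def renormalize(self) -> "TaxonProfile":
        """Return a copy whose per-sample abundances sum to exactly 1."""
        sums = self.data.sum(axis=0)
        if (sums <= 0).any():
            bad = list(sums.index[sums <= 0])
            raise ValueError(f"samples with zero total abundance: {bad}")
        return TaxonProfile(
            classifier_label=self.classifier_label,
            level=self.level,
            data=self.data.div(sums, axis=1),
            taxids=dict(self.taxids),
            lineages=dict(self.lineages),
        )

    def subset_taxa(self, taxa: Sequence[str]) -> "TaxonProfile":
        taxa = [t for t in self.taxa if t in set(taxa)]
        return TaxonProfile(
            classifier_label=self.classifier_label,
            level=self.level,
            data=self.data.loc[taxa],
            taxids={t: i for t, i in self.taxids.items() if t in set(taxa)},
            lineages={t: l for t, l in self.lineages.items() if t in set(taxa)},
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "taxon"
        out.to_csv(path, sep="\t")


@dataclass
class EvidenceCounts:
    """Per-cell classification evidence for a k-mer classifier profile.

    ``reads`` holds assigned read counts (taxa x samples, aligned with the
    profile); ``minimizers`` optionally holds distinct k-mer minimizer counts
    with the same shape.
    """

    reads: pd.DataFrame
    minimizers: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.reads.to_numpy(dtype=float) < 0).any():
            raise ValueError("negative read counts")
        if self.minimizers is not None and (
            self.minimizers.to_numpy(dtype=float) < 0
        ).any():
            raise ValueError("negative minimizer counts")


@dataclass
class DatabaseIndex:
    """Set of taxa available in a classifier's reference database."""

    classifier_label: str
    taxon_names: frozenset[str]

    @classmethod
    def from_names(cls, classifier_label: str, names: Iterable[str]) -> "DatabaseIndex":
        normalized = frozenset(normalize_taxon_name(n) for n in names)
        if not normalized:
            raise ValueError("empty database index")
        return cls(classifier_label, normalized)

    def __contains__(self, name: str) -> bool:
        return normalize_taxon_name(name) in self.taxon_names

    def __len__(self) -> int:
        return len(self.taxon_names)


def _detect_percent(values: np.ndarray) -> bool:
    # merged marker-gene tables report percentages (column sums near 100);
    # fractions never exceed 1 per cell
    return values.size > 0 and np.nanmax(values) > 1.0 + 1e-9


def read_metaphlan_profile(
    path: str | Path,
    level: str,
    retain_bins: bool = False,
    classifier_label: str = "metaphlan",
) -> TaxonProfile:
    """Parse a merged marker-gene abundance table at one taxonomic rank.

    Keeps only rows whose lineage terminates at ``level``; percentage values
    are converted to fractions.  Rows whose terminal label is a genome-bin
    identifier (no NCBI mapping) are dropped unless ``retain_bins``.
    """
    level = _check_level(level)
    path = Path(path)
    header: list[str] | None = None
    rows: list[tuple[str, str | None, list[float]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                stripped = line.lstrip("#")
                if "clade_name" in stripped.lower() or "sampleid" in stripped.lower():
                    header = stripped.split("\t")
                continue
            fields = line.split("\t")
            if header is None:
                # first non-comment line is the header
                header = fields
                continue
            lineage = fields[0]
            rest = fields[1:]
            taxid_field: str | None = None
            value_fields = rest
            if len(header) >= 2 and "tax_id" in header[1].lower():
                taxid_field = rest[0] if rest else None
                value_fields = rest[1:]
            components = lineage.split("|")
            parsed = [_LINEAGE_COMPONENT_RE.match(c) for c in components]
            if any(m is None for m in parsed):
                raise ValueError(
                    f"{path.name}:{lineno}: lineage component without rank "
                    f"prefix in {lineage!r}"
                )
            terminal = parsed[-1]
            assert terminal is not None
            rank = _PREFIX_TO_RANK[terminal.group(1)]
            if rank != level:
                continue
            name = terminal.group(2)
            if not retain_bins and is_genome_bin(name):
                continue
            try:
                values = [float(v) for v in value_fields]
            except ValueError as exc:
                raise ValueError(
                    f"{path.name}:{lineno}: non-numeric abundance value"
                ) from exc
            rows.append((name, taxid_field, values))

    if header is None:
        raise ValueError(f"{path.name}: no header line found")
    sample_cols = header[1:]
    if sample_cols and "tax_id" in sample_cols[0].lower():
        sample_cols = sample_cols[1:]
    if not sample_cols:
        raise ValueError(f"{path.name}: table contains no sample columns")

    if not rows:
        warnings.warn(
            f"no rows at level {level!r} in {path.name}; returning empty profile",
            stacklevel=2,
        )
        data = pd.DataFrame(
            np.empty((0, len(sample_cols))), index=[], columns=sample_cols
        )
        return TaxonProfile(classifier_label, level, data)

    names = [r[0] for r in rows]
    matrix = np.array([r[2] for r in rows], dtype=float)
    if matrix.shape[1] != len(sample_cols):
        raise ValueError(f"{path.name}: ragged rows vs header")
    if _detect_percent(matrix):
        matrix = matrix / 100.0
    data = pd.DataFrame(matrix, index=names, columns=sample_cols)
    # duplicate terminal names (distinct lineages converging) are summed
    if data.index.has_duplicates:
        data = data.groupby(level=0, sort=False).sum()

    taxids: dict[str, int] = {}
    for name, taxid_field, _ in rows:
        if taxid_field:
            terminal_id = taxid_field.split("|")[-1]
            if terminal_id and terminal_id not in ("-", "NA"):
                try:
                    taxids[name] = int(terminal_id)
                except ValueError:
                    pass
    lineages = {r[0]: "" for r in rows}
    return TaxonProfile(classifier_label, level, data, taxids=taxids, lineages=lineages)


_LEVEL_CODE = {
    "kingdom": "K",
    "phylum": "P",
    "class": "C",
    "order": "O",
    "family": "F",
    "genus": "G",
    "species": "S",
}


def read_bracken_report(
    paths: Sequence[str | Path],
    level: str,
    sample_names: Sequence[str] | None = None,
    classifier_label: str = "bracken",
) -> tuple[TaxonProfile, EvidenceCounts]:
    """Assemble per-sample k-mer abundance reports into one profile.

    Each report is a tab-delimited table with columns ``name``,
    ``taxonomy_id``, ``taxonomy_lvl``, read-count columns and
    ``fraction_total_reads``.  Samples missing a taxon receive abundance 0
    and read count 0.  Fractions are preserved as printed (no silent
    renormalization).
    """
    level = _check_level(level)
    paths = [Path(p) for p in paths]
    if sample_names is None:
        sample_names = [p.stem for p in paths]
    if len(sample_names) != len(paths):
        raise ValueError("sample_names length must match paths")
    if len(set(sample_names)) != len(sample_names):
        raise ValueError("duplicate sample names")

    per_sample_frac: dict[str, pd.Series] = {}
    per_sample_reads: dict[str, pd.Series] = {}
    taxids: dict[str, int] = {}
    for path, sample in zip(paths, sample_names):
        table = pd.read_csv(path, sep="\t")
        required = {"name", "taxonomy_id", "fraction_total_reads"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
        if "taxonomy_lvl" in table.columns:
            table = table[table["taxonomy_lvl"].astype(str).str.strip() == _LEVEL_CODE[level]]
        if table["taxonomy_id"].duplicated().any():
            dup = table.loc[table["taxonomy_id"].duplicated(), "taxonomy_id"].tolist()
            raise ValueError(f"{path.name}: duplicate taxonomy IDs {dup}")
        reads_col = "new_est_reads" if "new_est_reads" in table.columns else "kraken_assigned_reads"
        if reads_col not in table.columns:
            raise ValueError(f"{path.name}: no read-count column found")
        if (table[reads_col] < 0).any():
            raise ValueError(f"{path.name}: negative read counts")
        names = table["name"].astype(str).str.strip()
        per_sample_frac[sample] = pd.Series(
            table["fraction_total_reads"].to_numpy(dtype=float), index=names
        )
        per_sample_reads[sample] = pd.Series(
            table[reads_col].to_numpy(dtype=float), index=names
        )
        for name, taxid in zip(names, table["taxonomy_id"]):
            taxids[name] = int(taxid)

    abundance = pd.DataFrame(per_sample_frac).fillna(0.0)
    reads = pd.DataFrame(per_sample_reads).reindex(abundance.index).fillna(0.0)
    abundance = abundance[list(sample_names)]
    reads = reads[list(sample_names)]
    profile = TaxonProfile(classifier_label, level, abundance, taxids=taxids)
    return profile, EvidenceCounts(reads=reads)


def read_profile_tsv(
    path: str | Path, classifier_label: str, level: str
) -> TaxonProfile:
    """Read a plain taxon x sample TSV (as written by ``TaxonProfile.to_tsv``)."""
    data = pd.read_csv(path, sep="\t", index_col=0)
    if data.shape[1] == 0:
        raise ValueError(f"{Path(path).name}: no sample columns")
    data.index.name = None
    return TaxonProfile(classifier_label, level, data.astype(float))


def filter_low_evidence(
    profile: TaxonProfile,
    evidence: EvidenceCounts,
    min_log10_reads: float = 1.0,
    min_log10_minimizers: float | None = 3.0,
) -> TaxonProfile:
    """Zero out cells with insufficient classification evidence.

    A cell is removed when log10(read count) < ``min_log10_reads`` or, if
    minimizer counts are available, log10(unique minimizers) <
    ``min_log10_minimizers``.  Taxa zeroed everywhere are dropped and each
    sample is renormalized to sum to 1.  Idempotent at fixed thresholds.
    """
    if min_log10_reads < 0:
        raise ValueError("min_log10_reads must be non-negative")
    if min_log10_minimizers is not None and min_log10_minimizers < 0:
        raise ValueError("min_log10_minimizers must be non-negative")
    if min_log10_minimizers is not None and evidence.minimizers is None:
        raise ValueError(
            "minimizer threshold requested but no minimizer counts provided; "
            "pass min_log10_minimizers=None to filter on reads only"
        )

    abundance = profile.data.copy()
    reads = evidence.reads.reindex(index=abundance.index, columns=abundance.columns)
    present = abundance.to_numpy() > 0
    missing = present & reads.isna().to_numpy()
    if missing.any():
        i, j = np.argwhere(missing)[0]
        raise ValueError(
            f"no read evidence for cell (taxon={abundance.index[i]!r}, "
            f"sample={abundance.columns[j]!r})"
        )
    with np.errstate(divide="ignore"):
        keep = np.log10(reads.fillna(0.0).to_numpy()) >= min_log10_reads
    if min_log10_minimizers is not None:
        mins = evidence.minimizers.reindex(
            index=abundance.index, columns=abundance.columns
        )
        missing = present & mins.isna().to_numpy()
        if missing.any():
            i, j = np.argwhere(missing)[0]
            raise ValueError(
                f"no minimizer evidence for cell (taxon={abundance.index[i]!r}, "
                f"sample={abundance.columns[j]!r})"
            )
        with np.errstate(divide="ignore"):
            keep &= np.log10(mins.fillna(0.0).to_numpy()) >= min_log10_minimizers

    filtered = abundance.where(keep, 0.0)
    nonzero = (filtered.to_numpy() > 0).any(axis=1)
    filtered = filtered.loc[nonzero]
    sums = filtered.sum(axis=0)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise ValueError(
            f"all abundance removed from samples {bad}; relax thresholds"
        )
    filtered = filtered.div(sums, axis=1)
    kept = set(filtered.index)
    return TaxonProfile(
        classifier_label=profile.classifier_label,
        level=profile.level,
        data=filtered,
        taxids={t: i for t, i in profile.taxids.items() if t in kept},
        lineages={t: l for t, l in profile.lineages.items() if t in kept},
    )


@dataclass
class TaxonAlignment:
    """Pairing of taxa between two profiles.

    ``pairs`` maps matched taxa (name in a, name in b); ``unique_a`` /
    ``unique_b`` are names present in only one profile.  The partition is
    exact: ``common_a | unique_a`` equals the taxa of profile a.
    """

    pairs: list[tuple[str, str]]
    unique_a: list[str]
    unique_b: list[str]

    @property
    def common_a(self) -> set[str]:
        return {a for a, _ in self.pairs}

    @property
    def common_b(self) -> set[str]:
        return {b for _, b in self.pairs}

    @property
    def n_common(self) -> int:
        return len(self.pairs)


def align_taxa(a: TaxonProfile, b: TaxonProfile) -> TaxonAlignment:
    """Partition the taxa of two same-level profiles into common and unique.

    Matching uses NCBI taxonomy IDs when both sides provide one for a taxon,
    falling back to the normalized taxon name.
    """
    if a.level != b.level:
        raise ValueError(
            f"cannot align profiles at different levels ({a.level} vs {b.level})"
        )
    by_id = {taxid: name for name, taxid in b.taxids.items()}
    by_name: dict[str, str] = {}
    for name in b.taxa:
        by_name.setdefault(normalize_taxon_name(name), name)

    pairs: list[tuple[str, str]] = []
    unique_a: list[str] = []
    matched_b: set[str] = set()
    for name in a.taxa:
        taxid = a.taxids.get(name)
        target: str | None = None
        if taxid is not None and taxid in by_id:
            target = by_id[taxid]
        else:
            target = by_name.get(normalize_taxon_name(name))
        if target is not None and target not in matched_b:
            pairs.append((name, target))
            matched_b.add(target)
        else:
            unique_a.append(name)
    unique_b = [name for name in b.taxa if name not in matched_b]
    return TaxonAlignment(pairs=pairs, unique_a=unique_a, unique_b=unique_b)


@dataclass
class OverlapSummary:
    """Cross-classifier overlap accounting for two same-level profiles.

    Counts mirror the classic two-classifier comparison table: totals per
    classifier, in-common count, unique counts, and — when reference
    database indices are supplied — how many unique taxa the *other*
    classifier could in principle have found.  ``shared_abundance_a`` /
    ``_b`` give, per sample, the fraction of total relative abundance
    carried by in-common taxa.
    """

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    n_common: int
    n_unique_a: int
    n_unique_b: int
    unique_a_in_db_b: int | None
    unique_a_not_in_db_b: int | None
    unique_b_in_db_a: int | None
    unique_b_not_in_db_a: int | None
    shared_abundance_a: pd.Series
    shared_abundance_b: pd.Series

    def counts_frame(self) -> pd.DataFrame:
        rows = [
            {
                "classifier": self.label_a,
                "n_taxa": self.n_a,
                "n_common": self.n_common,
                "n_unique": self.n_unique_a,
                "unique_in_other_db": self.unique_a_in_db_b,
                "unique_not_in_other_db": self.unique_a_not_in_db_b,
            },
            {
                "classifier": self.label_b,
                "n_taxa": self.n_b,
                "n_common": self.n_common,
                "n_unique": self.n_unique_b,
                "unique_in_other_db": self.unique_b_in_db_a,
                "unique_not_in_other_db": self.unique_b_not_in_db_a,
            },
        ]
        return pd.DataFrame(rows)

    def shared_abundance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.shared_abundance_a.index,
                self.label_a: self.shared_abundance_a.to_numpy(),
                self.label_b: self.shared_abundance_b.reindex(
                    self.shared_abundance_a.index
                ).to_numpy(),
            }
        )


def _shared_fraction(profile: TaxonProfile, common: set[str]) -> pd.Series:
    totals = profile.data.sum(axis=0)
    if profile.n_taxa == 0 or not common:
        return pd.Series(0.0, index=profile.samples)
    shared = profile.data.loc[[t for t in profile.taxa if t in common]].sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac = (shared / totals).fillna(0.0)
    return frac


def overlap_summary(
    a: TaxonProfile,
    b: TaxonProfile,
    db_a: DatabaseIndex | None = None,
    db_b: DatabaseIndex | None = None,
) -> OverlapSummary:
    """Overlap counts, database-membership accounting, shared abundance."""
    alignment = align_taxa(a, b)

    def membership(unique: list[str], db: DatabaseIndex | None):
        if db is None:
            return None, None
        in_db = sum(1 for name in unique if name in db)
        return in_db, len(unique) - in_db

    ua_in, ua_out = membership(alignment.unique_a, db_b)
    ub_in, ub_out = membership(alignment.unique_b, db_a)
    return OverlapSummary(
        label_a=a.classifier_label,
        label_b=b.classifier_label,
        n_a=a.n_taxa,
        n_b=b.n_taxa,
        n_common=alignment.n_common,
        n_unique_a=len(alignment.unique_a),
        n_unique_b=len(alignment.unique_b),
        unique_a_in_db_b=ua_in,
        unique_a_not_in_db_b=ua_out,
        unique_b_in_db_a=ub_in,
        unique_b_not_in_db_a=ub_out,
        shared_abundance_a=_shared_fraction(a, alignment.common_a),
        shared_abundance_b=_shared_fraction(b, alignment.common_b),
    )
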