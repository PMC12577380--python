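"""Readers, writers and validated in-memory containers for pipeline tables.

All tabular formats are UTF-8 TSV with a header row; sample identifiers
occupy the first column of sample-indexed tables. Sequences are plain
FASTA. Every reader validates its input completely and raises a typed
error (:mod:`cprkit.errors`) on the first violation; writers produce
files that round-trip cell-for-cell through the matching reader.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, VocabularyError

logger = logging.getLogger(__name__)

TREATMENT_GROUPS = ("Auto", "Methylo", "Defined", "Complex", "InSitu", "Start")
OXYGEN_STATUSES = ("oxic", "anoxic")
WELL_IDS = ("H41", "H52", "other")

#: The six CPR classes detected in Hainich groundwater enrichments; membership
#: of a taxonomy `class` string in this list defines is_cpr. Overridable
#: everywhere a taxonomy is constructed.
DEFAULT_CPR_CLASSES = (
    "Parcubacteria",
    "ABY1",
    "Gracilibacteria",
    "Saccharimonadia",
    "Berkelbacteria",
    "Microgenomatia",
)

#: Default supplement vocabulary; unknown labels warn but do not fail.
DEFAULT_SUPPLEMENTS = (
    "thiosulfate",
    "ammonium",
    "nitrate",
    "nitrite",
    "methylamine",
    "methanol",
    "cellulose",
    "starch",
    "veratric_acid",
    "leaf_leachate",
    "soil_seepage",
    "necromass",
    "r2a",
)

#: Incubations start days after groundwater is pumped; field samples are
#: placed at a negative offset relative to incubation start (t = 0).
DEFAULT_INSITU_TIME_DAYS = -4.0

TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")

_EC_RE = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.((n?\d+)|-)$")


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} id {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# sample x ASV matrices
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Raw ASV read counts, samples in rows, ASVs in columns."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index.astype(str), "sample")
        _check_unique(df.columns.astype(str), "ASV")
        arr = df.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.all(np.equal(np.mod(arr, 1), 0)):
                    raise FormatError("count table contains non-integer cells")
                df = df.astype(np.int64)
                self.data = df
            if (df.to_numpy() < 0).any():
                r, c = np.argwhere(df.to_numpy() < 0)[0]
                raise FormatError(
                    f"negative count at sample {df.index[r]!r}, ASV {df.columns[c]!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class RelAbundanceTable:
    """Total-sum-scaled relative abundances; rows sum to 1 (or 0 if empty)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index.astype(str), "sample")
        _check_unique(self.data.columns.astype(str), "ASV")
        arr = self.data.to_numpy(dtype=float)
        if arr.size:
            if (arr < -1e-12).any() or (arr > 1 + 1e-9).any():
                raise FormatError("relative abundances must lie in [0, 1]")
            sums = arr.sum(axis=1)
            bad = ~(np.isclose(sums, 1.0, atol=1e-9) | np.isclose(sums, 0.0))
            if bad.any():
                raise FormatError(
                    f"relative-abundance rows must sum to 1 (or 0): "
                    f"sample {self.data.index[int(np.argmax(bad))]!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class AbsAbundanceTable:
    """qPCR-anchored absolute abundances in 16S gene copies per liter."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index.astype(str), "sample")
        _check_unique(self.data.columns.astype(str), "ASV")
        if self.data.size and (self.data.to_numpy(dtype=float) < 0).any():
            raise FormatError("absolute abundances must be >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced sample of one incubation experiment."""

    sample_id: str
    experiment_id: str
    treatment_group: str
    supplements: frozenset[str] = frozenset()
    oxygen_status: str = "oxic"
    time_days: float = 0.0
    replicate_id: str = "R1"
    well_id: str = "other"

    def __post_init__(self) -> None:
        if self.treatment_group not in TREATMENT_GROUPS:
            raise VocabularyError(
                f"unknown treatment group {self.treatment_group!r}; "
                f"expected one of {TREATMENT_GROUPS}"
            )
        if self.oxygen_status not in OXYGEN_STATUSES:
            raise VocabularyError(f"unknown oxygen status {self.oxygen_status!r}")
        if self.well_id not in WELL_IDS:
            raise VocabularyError(f"unknown well id {self.well_id!r}")
        if self.treatment_group != "InSitu" and self.time_days < 0:
            raise FormatError(
                f"sample {self.sample_id!r}: negative time for non-InSitu sample"
            )


def metadata_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Tabular view of sample records, indexed by sample id."""
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "experiment_id": [r.experiment_id for r in records],
            "treatment_group": [r.treatment_group for r in records],
            "supplements": [";".join(sorted(r.supplements)) for r in records],
            "oxygen_status": [r.oxygen_status for r in records],
            "time_days": [r.time_days for r in records],
            "replicate_id": [r.replicate_id for r in records],
            "well_id": [r.well_id for r in records],
        }
    ).set_index("sample_id")
    return df


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------


@dataclass
class TaxonomyTable:
    """SILVA-style rank assignments per ASV with a configured CPR class list.

    ``is_cpr`` is a pure function of the `class` rank string and
    ``cpr_classes``; empty class strings are normalized to "unclassified".
    """

    data: pd.DataFrame
    cpr_classes: tuple[str, ...] = DEFAULT_CPR_CLASSES

    def __post_init__(self) -> None:
        _check_unique(self.data.index.astype(str), "ASV")
        for rank in TAXONOMY_RANKS:
            if rank not in self.data.columns:
                raise FormatError(f"taxonomy table lacks rank column {rank!r}")
        cls = self.data["class"].fillna("").astype(str)
        self.data = self.data.copy()
        self.data["class"] = cls.where(cls != "", "unclassified")

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def is_cpr(self) -> pd.Series:
        return self.data["class"].isin(self.cpr_classes).rename("is_cpr")

    def rank_of(self, asv_id: str, rank: str = "class") -> str:
        return str(self.data.loc[asv_id, rank])

    def cpr_asvs(self) -> list[str]:
        mask = self.is_cpr
        return list(self.data.index[mask])


# ---------------------------------------------------------------------------
# qPCR totals
# ---------------------------------------------------------------------------


@dataclass
class QpcrTotals:
    """Total bacterial 16S rRNA gene copies per liter, per sample."""

    totals: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.totals.index.astype(str), "sample")
        vals = self.totals.to_numpy(dtype=float)
        if vals.size and (vals <= 0).any():
            bad = self.totals.index[int(np.argmax(vals <= 0))]
            raise FormatError(f"qPCR total must be > 0 (sample {bad!r})")
        self.totals = self.totals.astype(float).rename("total_copies_per_liter")

    def __getitem__(self, sample_id: str) -> float:
        return float(self.totals[sample_id])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.totals.index)


# ---------------------------------------------------------------------------
# EC reaction classification and MAG annotations
# ---------------------------------------------------------------------------

REACTION_CATEGORIES = ("oxic", "anoxic", "augmented")


def normalize_ec(ec: str) -> str:
    """Strip whitespace and an optional EC:/ec: prefix from an EC string."""
    ec = ec.strip()
    if ec[:3].lower() == "ec:":
        ec = ec[3:].strip()
    return ec


def is_valid_ec(ec: str) -> bool:
    return bool(_EC_RE.match(ec))


@dataclass
class ReactionClassTable:
    """EC number -> oxygen-dependence category (oxic / anoxic / augmented).

    Partial ECs such as ``1.4.3.-`` are legal keys and are matched only
    against identical partial strings, never expanded.
    """

    classes: dict[str, str]

    def __post_init__(self) -> None:
        for ec, cat in self.classes.items():
            if not is_valid_ec(ec):
                raise FormatError(f"syntactically invalid EC number {ec!r}")
            if cat not in REACTION_CATEGORIES:
                raise VocabularyError(
                    f"unknown reaction category {cat!r} for EC {ec}"
                )

    def category(self, ec: str) -> str | None:
        return self.classes.get(ec)

    def __len__(self) -> int:
        return len(self.classes)


@dataclass(frozen=True)
class Gene:
    gene_id: str
    ec_numbers: tuple[str, ...] = ()
    ko: str | None = None
    function_label: str | None = None


@dataclass
class MagAnnotation:
    """DRAM-style gene annotations for one metagenome-assembled genome."""

    mag_id: str
    taxon_class: str
    completeness: float
    contamination: float
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.completeness <= 100:
            raise FormatError(
                f"MAG {self.mag_id}: completeness {self.completeness} outside [0, 100]"
            )
        if self.contamination < 0:
            raise FormatError(f"MAG {self.mag_id}: negative contamination")
        _check_unique((g.gene_id for g in self.genes), f"gene (MAG {self.mag_id})")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse TSV {path}: {exc}") from exc


def read_count_table(path: str | Path) -> CountTable:
    """Read a samples x ASVs TSV of non-negative integer read counts."""
    raw = _read_tsv(path)
    try:
        data = raw.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric cell in count table {path}: {exc}") from exc
    return CountTable(data)


def read_rel_abundance(path: str | Path) -> RelAbundanceTable:
    """Read a samples x ASVs TSV of relative abundances."""
    return RelAbundanceTable(_read_tsv(path).apply(pd.to_numeric))


def read_abs_abundance(path: str | Path) -> AbsAbundanceTable:
    """Read a samples x ASVs TSV of absolute abundances (copies/L)."""
    return AbsAbundanceTable(_read_tsv(path).apply(pd.to_numeric))


def read_metadata(
    path: str | Path,
    *,
    insitu_time_days: float = DEFAULT_INSITU_TIME_DAYS,
    supplement_vocabulary: Sequence[str] = DEFAULT_SUPPLEMENTS,
) -> list[SampleRecord]:
    """Read sample metadata; supplements are a semicolon-separated list.

    InSitu rows may leave ``time_days`` empty; the configured negative
    offset is imputed. Unknown supplement labels warn; unknown treatment
    groups raise :class:`VocabularyError`.
    """
    df = _read_tsv(path)
    records: list[SampleRecord] = []
    vocab = set(supplement_vocabulary)
    for sample_id, row in df.iterrows():
        supplements = frozenset(
            s.strip().lower() for s in str(row.get("supplements", "")).split(";") if s.strip()
        )
        unknown = supplements - vocab
        if unknown:
            logger.warning(
                "sample %s: supplements outside vocabulary: %s",
                sample_id,
                ", ".join(sorted(unknown)),
            )
        group = str(row["treatment_group"])
        t_raw = str(row.get("time_days", "")).strip()
        if t_raw == "":
            if group == "InSitu":
                time_days = float(insitu_time_days)
            else:
                raise FormatError(
                    f"sample {sample_id!r}: missing time_days for non-InSitu sample"
                )
        else:
            time_days = float(t_raw)
        records.append(
            SampleRecord(
                sample_id=str(sample_id),
                experiment_id=str(row["experiment_id"]),
                treatment_group=group,
                supplements=supplements,
                oxygen_status=str(row["oxygen_status"]),
                time_days=time_days,
                replicate_id=str(row.get("replicate_id", "R1")),
                well_id=str(row.get("well_id", "other")),
            )
        )
    _check_unique((r.sample_id for r in records), "sample")
    return records


def read_taxonomy(
    path: str | Path, cpr_classes: Sequence[str] = DEFAULT_CPR_CLASSES
) -> TaxonomyTable:
    """Read a per-ASV taxonomy TSV with SILVA-style rank columns."""
    return TaxonomyTable(_read_tsv(path), tuple(cpr_classes))


def read_qpcr(path: str | Path) -> QpcrTotals:
    """Read per-sample total 16S gene copies per liter."""
    df = _read_tsv(path)
    col = df.columns[0]
    try:
        totals = df[col].astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric qPCR total in {path}: {exc}") from exc
    return QpcrTotals(totals)


def read_reaction_classes(path: str | Path) -> ReactionClassTable:
    """Read an EC -> category table (columns: ec, category)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "ec" not in df.columns or "category" not in df.columns:
        raise FormatError(f"reaction-class table {path} needs 'ec' and 'category' columns")
    classes: dict[str, str] = {}
    for _, row in df.iterrows():
        ec = normalize_ec(row["ec"])
        if ec in classes and classes[ec] != row["category"]:
            raise FormatError(f"EC {ec} assigned to two categories")
        classes[ec] = row["category"]
    return ReactionClassTable(classes)


def read_annotations(path: str | Path, *, ec_delimiter: str = ";") -> list[MagAnnotation]:
    """Read a flat gene-annotation TSV into per-MAG annotation objects.

    Expected columns: mag_id, taxon_class, completeness, contamination,
    gene_id, ec, and optionally ko and function. The EC cell may hold
    zero, one or several delimiter-separated EC numbers. Malformed EC
    strings are dropped from the gene with a logged warning; the gene is
    kept.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"mag_id", "taxon_class", "completeness", "contamination", "gene_id", "ec"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"annotation table {path} lacks columns {sorted(missing)}")
    mags: dict[str, MagAnnotation] = {}
    genes_by_mag: dict[str, list[Gene]] = {}
    for _, row in df.iterrows():
        mag_id = row["mag_id"]
        if mag_id not in mags:
            mags[mag_id] = MagAnnotation(
                mag_id=mag_id,
                taxon_class=row["taxon_class"],
                completeness=float(row["completeness"]),
                contamination=float(row["contamination"]),
            )
            genes_by_mag[mag_id] = []
        ecs: list[str] = []
        for token in str(row["ec"]).split(ec_delimiter):
            token = normalize_ec(token)
            if not token:
                continue
            if not is_valid_ec(token):
                logger.warning(
                    "MAG %s gene %s: dropping malformed EC %r",
                    mag_id,
                    row["gene_id"],
                    token,
                )
                continue
            ecs.append(token)
        genes_by_mag[mag_id].append(
            Gene(
                gene_id=row["gene_id"],
                ec_numbers=tuple(ecs),
                ko=row.get("ko") or None,
                function_label=row.get("function") or None,
            )
        )
    out = []
    for mag_id, mag in mags.items():
        out.append(
            MagAnnotation(
                mag_id=mag.mag_id,
                taxon_class=mag.taxon_class,
                completeness=mag.completeness,
                contamination=mag.contamination,
                genes=genes_by_mag[mag_id],
            )
        )
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered id -> uppercase sequence mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def read_fasta_with_taxonomy(
    fasta_path: str | Path,
    taxonomy_path: str | Path,
    cpr_classes: Sequence[str] = DEFAULT_CPR_CLASSES,
) -> tuple[dict[str, str], TaxonomyTable]:
    """Read a reference sequence set and its taxonomy; ids must agree."""
    seqs = read_fasta(fasta_path)
    tax = read_taxonomy(taxonomy_path, cpr_classes)
    missing = set(seqs) - set(tax.asv_ids)
    if missing:
        raise FormatError(
            f"sequences without taxonomy entries: {sorted(missing)[:5]}"
        )
    return seqs, tax


# ---------------------------------------------------------------------------
# writers (inverse of the readers, cell-for-cell)
# ---------------------------------------------------------------------------


def _write_tsv(df: pd.DataFrame, path: str | Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=index_label, lineterminator="\n")


def write_count_table(table: CountTable, path: str | Path) -> None:
    _write_tsv(table.data, path, "sample_id")


def write_rel_abundance(table: RelAbundanceTable, path: str | Path) -> None:
    _write_tsv(table.data, path, "sample_id")


def write_abs_abundance(table: AbsAbundanceTable, path: str | Path) -> None:
    _write_tsv(table.data, path, "sample_id")


def write_metadata(records: Sequence[SampleRecord], path: str | Path) -> None:
    _write_tsv(metadata_frame(records), path, "sample_id")


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    _write_tsv(tax.data[list(TAXONOMY_RANKS)], path, "asv_id")


def write_qpcr(qpcr: QpcrTotals, path: str | Path) -> None:
    _write_tsv(qpcr.totals.to_frame(), path, "sample_id")


def write_reaction_classes(table: ReactionClassTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {"ec": list(table.classes), "category": list(table.classes.values())}
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_annotations(mags: Sequence[MagAnnotation], path: str | Path) -> None:
    rows = []
    for mag in mags:
        for g in mag.genes:
            rows.append(
                {
                    "mag_id": mag.mag_id,
                    "taxon_class": mag.taxon_class,
                    "completeness": mag.completeness,
                    "contamination": mag.contamination,
                    "gene_id": g.gene_id,
                    "ec": ";".join(g.ec_numbers),
                    "ko": g.ko or "",
                    "function": g.function_label or "",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
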