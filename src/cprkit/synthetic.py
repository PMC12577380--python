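"""Synthetic pipeline inputs with planted ground truth.

The generator emulates the statistical structure of groundwater
enrichment incubations: latent per-ASV absolute 16S copy trajectories
follow exponential growth N_i(t) = N_i(0) e^{k_i t} with multiplicative
lognormal noise, total copies per sample are observed through a noisy
qPCR measurement, and sequencing counts arise from multinomial sampling
of the latent composition at a fixed read depth. Reference 16S sequence
sets carry primer sites with planted mismatch patterns, and MAG
annotation tables carry planted EC-category memberships, so every
downstream stage can be scored against known truth.

All randomness flows from a single seed through named, spawned
sub-streams, so adding one simulation never perturbs another and
identical configurations give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import (
    DEFAULT_CPR_CLASSES,
    TAXONOMY_RANKS,
    CountTable,
    Gene,
    MagAnnotation,
    QpcrTotals,
    ReactionClassTable,
    SampleRecord,
    TaxonomyTable,
)

# taxonomy scaffolding used when labeling simulated ASVs
_CPR_ORDERS = {
    "Parcubacteria": ("UBA9983", "Kaiserbacteria", "Nomurabacteria"),
    "ABY1": ("Magasanikbacteria", "Uhrbacteria"),
    "Gracilibacteria": ("Absconditabacterales",),
    "Saccharimonadia": ("Saccharimonadales",),
    "Berkelbacteria": ("UBA1384",),
    "Microgenomatia": ("Candidatus_Woesebacteria",),
}
_NONCPR_TAXA = (
    ("Gammaproteobacteria", "Burkholderiales"),
    ("Gammaproteobacteria", "Pseudomonadales"),
    ("Bacteroidia", "Chitinophagales"),
    ("Bacteroidia", "Flavobacteriales"),
    ("Alphaproteobacteria", "Rhizobiales"),
    ("Nitrospiria", "Nitrospirales"),
    ("Verrucomicrobiae", "Verrucomicrobiales"),
    ("Planctomycetes", "Pirellulales"),
)

_STREAMS = ("rates", "n0", "latent", "qpcr", "counts", "refdb", "mags", "coocc")


@dataclass(frozen=True)
class PrimerSiteDesign:
    """Planted primer-site mismatch composition for one taxonomy class.

    True coverage is forced by construction:
    (n_perfect + n_two_mismatch_internal) / total.
    """

    n_perfect: int = 8
    n_two_mismatch_internal: int = 1
    n_3prime_broken: int = 1
    n_three_mismatch: int = 0

    @property
    def total(self) -> int:
        return (
            self.n_perfect
            + self.n_two_mismatch_internal
            + self.n_3prime_broken
            + self.n_three_mismatch
        )

    @property
    def true_coverage(self) -> float:
        return (self.n_perfect + self.n_two_mismatch_internal) / self.total


@dataclass(frozen=True)
class MagDesign:
    """Planted EC composition for one simulated MAG."""

    mag_id: str
    taxon_class: str
    completeness: float
    contamination: float
    n_oxic: int = 3
    n_anoxic: int = 15
    n_augmented: int = 12
    n_unclassified: int = 3
    n_duplicate_genes: int = 2
    n_multi_ec_genes: int = 2


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults mirror the incubation setting the pipeline targets:
    multi-week oligotrophic groundwater incubations sampled at weekly
    intervals in triplicate, a community of CPR and non-CPR ASVs in
    which most organisms double in roughly two weeks while a few grow
    fast and a quarter decline, total copy numbers around 10^7-10^8 per
    liter, and MiSeq-scale read depths.

    Growth rates (per day): CPR rates are drawn so doubling times are
    lognormal around 15 days, non-CPR around 13.5 days; a
    ``decline_fraction`` of ASVs receives a negative rate. Measurement
    noise defaults (sigma on the natural-log scale) are 0.25 for latent
    abundances and 0.2 for qPCR totals; measurement-error magnitudes
    are rarely reported for such assays, so these are explicit,
    overridable choices.
    """

    seed: int = 0
    n_asv_cpr: int = 30
    n_asv_noncpr: int = 70
    n_experiments: int = 4
    time_points: tuple[float, ...] = (0.0, 7.0, 14.0, 21.0, 28.0)
    n_replicates: int = 3
    growth_rates: np.ndarray | None = None  # explicit per-ASV k, overrides sampling
    initial_abundances: np.ndarray | None = None  # explicit per-ASV N_i(0)
    median_doubling_days_cpr: float = 15.0
    median_doubling_days_noncpr: float = 13.5
    rate_sd_log: float = 0.6
    decline_fraction: float = 0.25
    n0_median: float = 1.0e5
    n0_sd_log: float = 1.5
    noise_sd_log: float = 0.25
    qpcr_noise_sd_log: float = 0.2
    depth: int | None = 30000
    planted_pairs: int = 0  # CPR ASVs whose latent tracks a non-CPR partner
    primer_design: Mapping[str, PrimerSiteDesign] = field(
        default_factory=lambda: {c: PrimerSiteDesign() for c in DEFAULT_CPR_CLASSES}
    )
    amplicon_insert_range: tuple[int, int] = (300, 400)
    flank_length: int = 25
    mag_designs: tuple[MagDesign, ...] = ()

    def __post_init__(self) -> None:
        if self.n_asv_cpr < 0 or self.n_asv_noncpr < 0 or self.n_replicates < 1:
            raise ConfigError("ASV and replicate counts must be non-negative/positive")
        if any(b <= a for a, b in zip(self.time_points, self.time_points[1:])):
            raise ConfigError("time_points must be strictly increasing")
        if self.noise_sd_log < 0 or self.qpcr_noise_sd_log < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        n_asv = self.n_asv_cpr + self.n_asv_noncpr
        if self.depth == 0 and n_asv > 0:
            raise ConfigError("sequencing depth 0 with ASVs present")
        if self.planted_pairs > min(self.n_asv_cpr, self.n_asv_noncpr):
            raise ConfigError("more planted pairs than available ASVs")

    def streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


@dataclass
class GroundTruth:
    """Planted truth, deterministically derivable from SynthConfig + seed."""

    true_k: pd.Series | None = None
    true_n0: pd.Series | None = None
    true_totals: pd.Series | None = None
    latent: pd.DataFrame | None = None  # samples x ASVs latent copies/L
    planted_pairs: list[tuple[str, str]] = field(default_factory=list)
    primer_coverage: dict[str, float] = field(default_factory=dict)
    amplifiable: dict[str, bool] = field(default_factory=dict)
    mag_truth: pd.DataFrame | None = None


def _default_mag_designs() -> tuple[MagDesign, ...]:
    """Three MAGs per CPR class; the first four straddle the quality gates."""
    designs: list[MagDesign] = []
    boundary = [(50.0, 5.0), (49.9, 5.0), (80.0, 10.0), (80.0, 10.1)]
    i = 0
    for cls in DEFAULT_CPR_CLASSES:
        for j in range(3):
            if i < len(boundary):
                comp, cont = boundary[i]
            else:
                comp, cont = 60.0 + (i * 7) % 35, float(i % 9)
            designs.append(
                MagDesign(
                    mag_id=f"MAG{i:03d}",
                    taxon_class=cls,
                    completeness=comp,
                    contamination=cont,
                    n_oxic=2 + (i % 6),
                    n_anoxic=10 + (i * 3) % 11,
                    n_augmented=8 + (i * 2) % 8,
                    n_unclassified=i % 4,
                )
            )
            i += 1
    return tuple(designs)


def _asv_taxonomy(config: SynthConfig) -> TaxonomyTable:
    rows = []
    cpr_items = [
        (cls, order) for cls, orders in _CPR_ORDERS.items() for order in orders
    ]
    for i in range(config.n_asv_cpr):
        cls, order = cpr_items[i % len(cpr_items)]
        rows.append(("Bacteria", "Patescibacteria", cls, order, f"{order}_fam", ""))
    for i in range(config.n_asv_noncpr):
        cls, order = _NONCPR_TAXA[i % len(_NONCPR_TAXA)]
        rows.append(("Bacteria", "OtherPhylum", cls, order, f"{order}_fam", ""))
    asv_ids = [f"ASV{i:04d}" for i in range(len(rows))]
    df = pd.DataFrame(rows, columns=list(TAXONOMY_RANKS), index=pd.Index(asv_ids, name="asv_id"))
    return TaxonomyTable(df)


def _sample_rates(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_asv_cpr + config.n_asv_noncpr
    ln2 = np.log(2.0)
    k = np.empty(n)
    med = np.where(
        np.arange(n) < config.n_asv_cpr,
        ln2 / config.median_doubling_days_cpr,
        ln2 / config.median_doubling_days_noncpr,
    )
    k = med * np.exp(rng.normal(0.0, config.rate_sd_log, size=n))
    decliners = rng.random(n) < config.decline_fraction
    k[decliners] *= -1.0
    return k


def simulate_experiment(
    config: SynthConfig,
) -> tuple[CountTable, list[SampleRecord], QpcrTotals, TaxonomyTable, GroundTruth]:
    """Simulate count table, metadata, qPCR totals and taxonomy.

    Experiments alternate between thiosulfate/ammonium-amended oxic
    ("Auto") and methylamine-amended anoxic ("Methylo") treatments, the
    two treatment families for which qPCR anchoring is available. Samples at t = 0 form the "Start" group. ``depth=None``
    is the infinite-depth surrogate: counts are the rounded latent
    copy numbers, so with zero noise the anchored absolute abundances
    reproduce N_i(0)e^{kt} up to rounding.
    """
    streams = config.streams()
    n_asv = config.n_asv_cpr + config.n_asv_noncpr
    tax = _asv_taxonomy(config)
    asv_ids = tax.asv_ids

    if config.growth_rates is not None:
        k = np.asarray(config.growth_rates, dtype=float)
        if k.shape != (n_asv,):
            raise ConfigError("growth_rates length must equal total ASV count")
    else:
        k = _sample_rates(config, streams["rates"])
    if config.initial_abundances is not None:
        n0 = np.asarray(config.initial_abundances, dtype=float)
        if n0.shape != (n_asv,):
            raise ConfigError("initial_abundances length must equal total ASV count")
    else:
        n0 = config.n0_median * np.exp(
            streams["n0"].normal(0.0, config.n0_sd_log, size=n_asv)
        )

    pairs: list[tuple[str, str]] = []
    pair_idx: list[tuple[int, int]] = []
    for p in range(config.planted_pairs):
        a, b = p, config.n_asv_cpr + p
        pair_idx.append((a, b))
        pairs.append((asv_ids[a], asv_ids[b]))

    records: list[SampleRecord] = []
    latent_rows: list[np.ndarray] = []
    rng_latent = streams["latent"]
    for e in range(config.n_experiments):
        auto = e % 2 == 0
        treatment = "Auto" if auto else "Methylo"
        supplements = (
            frozenset({"thiosulfate", "ammonium"}) if auto else frozenset({"methylamine"})
        )
        oxy = "oxic" if auto else "anoxic"
        well = "H41" if auto else "H52"
        for t in config.time_points:
            for r in range(config.n_replicates):
                sid = f"E{e}_T{t:g}_R{r + 1}"
                group = "Start" if t == 0 else treatment
                records.append(
                    SampleRecord(
                        sample_id=sid,
                        experiment_id=f"E{e}",
                        treatment_group=group,
                        supplements=supplements,
                        oxygen_status=oxy,
                        time_days=float(t),
                        replicate_id=f"R{r + 1}",
                        well_id=well,
                    )
                )
                noise = (
                    np.exp(rng_latent.normal(0.0, config.noise_sd_log, size=n_asv))
                    if config.noise_sd_log > 0
                    else np.ones(n_asv)
                )
                lat = n0 * np.exp(k * t) * noise
                for a, b in pair_idx:  # planted co-occurrence: shared trajectory
                    lat[a] = 0.5 * lat[b]
                latent_rows.append(lat)

    sample_ids = [r.sample_id for r in records]
    latent = pd.DataFrame(latent_rows, index=pd.Index(sample_ids, name="sample_id"), columns=asv_ids)
    true_totals = latent.sum(axis=1)

    qpcr_noise = (
        np.exp(streams["qpcr"].normal(0.0, config.qpcr_noise_sd_log, size=len(records)))
        if config.qpcr_noise_sd_log > 0
        else np.ones(len(records))
    )
    qpcr = QpcrTotals(pd.Series(true_totals.to_numpy() * qpcr_noise, index=latent.index))

    rng_counts = streams["counts"]
    counts = np.empty((len(records), n_asv), dtype=np.int64)
    for i in range(len(records)):
        lat = latent.iloc[i].to_numpy()
        if config.depth is None:
            counts[i] = np.round(lat).astype(np.int64)
        else:
            p = lat / lat.sum()
            counts[i] = rng_counts.multinomial(config.depth, p)
    count_table = CountTable(pd.DataFrame(counts, index=latent.index.copy(), columns=asv_ids))

    truth = GroundTruth(
        true_k=pd.Series(k, index=asv_ids, name="k_per_day"),
        true_n0=pd.Series(n0, index=asv_ids, name="n0_copies_per_liter"),
        true_totals=true_totals.rename("true_total_copies_per_liter"),
        latent=latent,
        planted_pairs=pairs,
    )
    return count_table, records, qpcr, tax, truth


# ---------------------------------------------------------------------------
# reference sequence database with planted primer sites
# ---------------------------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _realize(primer_seq: str, rng: np.random.Generator) -> str:
    """Pick one concrete sequence compatible with a degenerate primer."""
    return "".join(
        _IUPAC[b][rng.integers(len(_IUPAC[b]))] for b in primer_seq.upper()
    )


def _mismatch_base(primer_base: str, rng: np.random.Generator) -> str:
    allowed = set(_IUPAC[primer_base.upper()])
    pool = [b for b in "ACGT" if b not in allowed]
    return pool[rng.integers(len(pool))]


def _plant_site(
    primer_seq: str, pattern: str, rng: np.random.Generator
) -> str:
    """Concrete target-strand site for one planted mismatch pattern.

    Patterns: 'perfect', 'two_internal' (two mismatches outside the
    3'-terminal dinucleotide), '3prime_broken' (one mismatch inside the
    terminal dinucleotide), 'three_internal'.
    """
    site = list(_realize(primer_seq, rng))
    L = len(site)
    # a mismatch is only plantable where the primer base is not fully
    # degenerate (no base conflicts with N)
    internal = np.array(
        [i for i in range(L - 2) if len(_IUPAC[primer_seq[i].upper()]) < 4]
    )
    terminal = [i for i in (L - 2, L - 1) if len(_IUPAC[primer_seq[i].upper()]) < 4]
    if pattern == "perfect":
        positions: Sequence[int] = ()
    elif pattern == "two_internal":
        positions = rng.choice(internal, size=2, replace=False)
    elif pattern == "3prime_broken":
        if not terminal:
            raise ConfigError("cannot break a fully degenerate 3' dinucleotide")
        positions = [terminal[int(rng.integers(len(terminal)))]]
    elif pattern == "three_internal":
        positions = rng.choice(internal, size=3, replace=False)
    else:  # pragma: no cover
        raise ConfigError(f"unknown planted pattern {pattern!r}")
    for pos in positions:
        site[pos] = _mismatch_base(primer_seq[pos], rng)
    return "".join(site)


def simulate_reference_db(
    config: SynthConfig,
    fwd_sequence: str = "CCTACGGGNGGCWGCAG",
    rev_sequence: str = "GACTACHVGGGTATCTAATCC",
) -> tuple[dict[str, str], TaxonomyTable, GroundTruth]:
    """Simulate a reference 16S set with planted primer-site mismatches.

    Each sequence carries a forward-primer site and the reverse
    complement of a reverse-primer site separated by a random insert;
    mismatches are planted on the forward site only, in the pattern
    counts given by ``config.primer_design`` per taxonomy class. True
    per-class coverage is (n_perfect + n_two_mismatch_internal) / total.
    """
    rng = config.streams()["refdb"]
    lo, hi = config.amplicon_insert_range
    if lo < 1 or hi < lo:
        raise ConfigError("amplicon_insert_range must be positive and ordered")
    seqs: dict[str, str] = {}
    tax_rows = []
    truth = GroundTruth()
    patterns = (
        ("perfect", "n_perfect", True),
        ("two_internal", "n_two_mismatch_internal", True),
        ("3prime_broken", "n_3prime_broken", False),
        ("three_internal", "n_three_mismatch", False),
    )
    for cls, design in config.primer_design.items():
        if design.total == 0:
            continue
        idx = 0
        for pattern, attr, amplifiable in patterns:
            for _ in range(getattr(design, attr)):
                seq_id = f"{cls}_seq{idx:03d}"
                idx += 1
                fwd_site = _plant_site(fwd_sequence, pattern, rng)
                rev_site = _realize(rev_sequence, rng)
                rev_site_rc = rev_site.translate(_COMPLEMENT)[::-1]
                insert = "".join(
                    "ACGT"[j] for j in rng.integers(4, size=int(rng.integers(lo, hi + 1)))
                )
                flank5 = "".join("ACGT"[j] for j in rng.integers(4, size=config.flank_length))
                flank3 = "".join("ACGT"[j] for j in rng.integers(4, size=config.flank_length))
                seqs[seq_id] = flank5 + fwd_site + insert + rev_site_rc + flank3
                tax_rows.append(
                    (seq_id, "Bacteria", "Patescibacteria", cls, f"{cls}_order", "", "")
                )
                truth.amplifiable[seq_id] = amplifiable
        truth.primer_coverage[cls] = design.true_coverage
    df = pd.DataFrame(
        [r[1:] for r in tax_rows],
        columns=list(TAXONOMY_RANKS),
        index=pd.Index([r[0] for r in tax_rows], name="asv_id"),
    )
    return seqs, TaxonomyTable(df), truth


# ---------------------------------------------------------------------------
# MAG annotations with planted EC category membership
# ---------------------------------------------------------------------------

_EC_POOL_PREFIX = {"oxic": "1.14.13", "anoxic": "2.7.1", "augmented": "4.1.2"}


def simulate_mag_annotations(
    config: SynthConfig,
) -> tuple[list[MagAnnotation], ReactionClassTable, GroundTruth]:
    """Simulate DRAM-style MAG gene tables plus the EC category table.

    Each MAG receives the planted numbers of distinct single-EC genes
    per category, extra genes duplicating an already-used EC (to
    exercise per-MAG deduplication), genes carrying two EC numbers (to
    exercise the multi-EC exclusion rule), and ECs absent from the
    classification table. Completeness/contamination values straddle
    the 50% / 10% quality gates in the default design.
    """
    designs = config.mag_designs or _default_mag_designs()
    rng = config.streams()["mags"]
    pool_size = 400
    pools = {
        cat: [f"{pre}.{i + 1}" for i in range(pool_size)]
        for cat, pre in _EC_POOL_PREFIX.items()
    }
    classes = {ec: cat for cat, pool in pools.items() for ec in pool}
    table = ReactionClassTable(classes)

    mags: list[MagAnnotation] = []
    truth_rows = []
    for d in designs:
        genes: list[Gene] = []
        gid = 0
        used: list[str] = []
        for cat, n in (
            ("oxic", d.n_oxic),
            ("anoxic", d.n_anoxic),
            ("augmented", d.n_augmented),
        ):
            chosen = rng.choice(len(pools[cat]), size=n, replace=False)
            for j in chosen:
                ec = pools[cat][int(j)]
                genes.append(Gene(f"{d.mag_id}_g{gid:04d}", (ec,)))
                used.append(ec)
                gid += 1
        for u in range(d.n_unclassified):
            genes.append(Gene(f"{d.mag_id}_g{gid:04d}", (f"9.9.9.{gid + 1}",)))
            gid += 1
        for _ in range(min(d.n_duplicate_genes, len(used))):
            ec = used[int(rng.integers(len(used)))]
            genes.append(Gene(f"{d.mag_id}_g{gid:04d}", (ec,)))
            gid += 1
        for _ in range(d.n_multi_ec_genes):
            e1 = pools["oxic"][int(rng.integers(pool_size))]
            e2 = pools["anoxic"][int(rng.integers(pool_size))]
            genes.append(Gene(f"{d.mag_id}_g{gid:04d}", (e1, e2)))
            gid += 1
        mags.append(
            MagAnnotation(
                mag_id=d.mag_id,
                taxon_class=d.taxon_class,
                completeness=d.completeness,
                contamination=d.contamination,
                genes=genes,
            )
        )
        truth_rows.append(
            {
                "mag_id": d.mag_id,
                "taxon_class": d.taxon_class,
                "n_oxic": d.n_oxic,
                "n_anoxic": d.n_anoxic,
                "n_augmented": d.n_augmented,
                "n_unclassified": d.n_unclassified,
                "passes_filter": d.completeness >= 50.0 and d.contamination <= 10.0,
            }
        )
    truth = GroundTruth(mag_truth=pd.DataFrame(truth_rows).set_index("mag_id"))
    return mags, table, truth


def with_seed(config: SynthConfig, seed: int) -> SynthConfig:
    """Copy a configuration with a different seed."""
    return replace(config, seed=seed)
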