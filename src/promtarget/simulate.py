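"""Synthetic promoter-array, expression and sequence data with known truth.

The generator emulates the statistical structure the downstream analysis
assumes: a promoter tiling array whose probes are grouped into sequence IDs
spanning -3.75 kb..+0.75 kb around each gene's TSS; per-probe log2
enrichment values for a small number of ChIP replicates; WT/KO log2
expression matrices with one to three probe sets per gene; and promoter
sequences with motifs planted at exact TSS-relative positions.

Noise is i.i.d. Gaussian on the log2 scale throughout (the analysis operates
on log-transformed values); there are no probe-affinity, GC or spatial-array
effects.  Spiked binding is a constant log2 shift over a contiguous run of
probes -- by default 8-12 probes, i.e. an enriched region of roughly
0.8-1.2 kb at the design's ~100 bp probe spacing, the width of a typical
promoter-array binding peak.  All generators are deterministic given the
configuration seed; each draws from its own seed stream so the outputs do
not depend on the order in which generators are invoked.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .motifs import (
    DEFAULT_MOTIFS,
    IUPAC_CODES,
    Motif,
    position_to_offset,
    reverse_complement,
)
from .peaks import WINDOW_SIZE, ArrayDesign

# seed-stream tags (kept below 2**31 together with any user seed)
_STREAM_DESIGN, _STREAM_TRUTH, _STREAM_CHIP, _STREAM_EXPR, _STREAM_PROM = range(5)

_SLAB = 50_000  # per-sequence-ID genomic slab; guarantees >10 kb separation
_CHROMS = tuple(f"chr{i}" for i in range(1, 20))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic data.

    Ranges are inclusive ``(lo, hi)`` tuples.  Defaults mirror the promoter
    array being emulated (5-35 probes of 49-74 bp per sequence ID, two ChIP
    replicates, four WT and four KO expression replicates) at desk scale
    (hundreds of sequence IDs rather than tens of thousands); fractions of
    spiked sequence IDs/genes default to the rates observed on the real
    platform (about a quarter of promoters bound, half of probe sets
    differential).
    """

    seed: int = 0
    n_seq_ids: int = 200
    probes_per_id: tuple[int, int] = (5, 35)
    probe_length: tuple[int, int] = (49, 74)
    inter_probe_gap: tuple[int, int] = (100, 3700)  # start-to-start spacing
    n_replicates_chip: int = 2
    n_wt: int = 4
    n_ko: int = 4
    probe_sets_per_gene: tuple[int, int] = (1, 3)
    noise_sd_chip: float = 0.25
    noise_sd_expr: float = 0.25
    bound_fraction: float = 0.25
    de_fraction: float = 0.5
    chip_effect: float = 0.5
    expr_effect: float = 1.0
    spike_probes: tuple[int, int] = (8, 12)
    intergenic_fraction: float = 0.03
    n_ambiguous: int = 0
    motif_plants: tuple[tuple[str, int], ...] = ()
    promoter_span: tuple[int, int] = (-3750, 750)

    def __post_init__(self) -> None:
        for name in ("n_seq_ids", "n_replicates_chip", "n_wt", "n_ko"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "probes_per_id",
            "probe_length",
            "inter_probe_gap",
            "probe_sets_per_gene",
            "spike_probes",
        ):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} range ({lo}, {hi}) is empty or invalid")
        for name in ("bound_fraction", "de_fraction", "intergenic_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.probes_per_id[0] < WINDOW_SIZE:
            raise ValueError(
                f"probes_per_id lower bound must be >= window size {WINDOW_SIZE}"
            )
        if self.spike_probes[0] < WINDOW_SIZE:
            raise ValueError(f"spike run must cover >= {WINDOW_SIZE} probes")
        if self.promoter_span[0] >= self.promoter_span[1]:
            raise ValueError("promoter span is empty")
        span = self.promoter_span[1] - self.promoter_span[0]
        worst = (self.probes_per_id[1] - 1) * self.inter_probe_gap[0] + self.probe_length[1]
        if worst > span:
            raise ValueError(
                f"impossible geometry: {self.probes_per_id[1]} probes at minimum "
                f"spacing {self.inter_probe_gap[0]} bp need {worst} bp but the "
                f"promoter span is {span} bp"
            )

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    @property
    def span_length(self) -> int:
        return self.promoter_span[1] - self.promoter_span[0]

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """What was actually spiked, resolvable against the generated files.

    ``bound``: seq_id, spike_start (probe index), spike_len;
    ``de``: gene, effect (signed log2 WT-KO);
    ``planted``: seq_id, motif, position, strand (filled by the promoter
    generator); ``ambiguous``: genes given a sign-flipped probe set.
    """

    bound: pd.DataFrame
    de: pd.DataFrame
    planted: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["seq_id", "motif", "position", "strand"]
        )
    )
    ambiguous: list[str] = field(default_factory=list)

    @property
    def bound_seq_ids(self) -> set[str]:
        return set(self.bound["seq_id"])

    @property
    def de_genes(self) -> dict[str, float]:
        return dict(zip(self.de["gene"], self.de["effect"]))


def _seq_gene(i: int) -> tuple[str, str]:
    return f"SEQ{i:05d}", f"G{i:05d}"


def generate_array_design(
    config: SimulationConfig,
) -> tuple[ArrayDesign, pd.DataFrame]:
    """Generate the probe table and gene annotation.

    Every sequence ID occupies its own 50 kb genomic slab (so no foreign
    gene lies within 10 kb of it) and, unless intergenic, is paired with one
    gene whose TSS anchors the promoter span and whose coding interval
    starts just downstream of the TSS.  Probe start-to-start spacings are
    drawn from ``inter_probe_gap``, capped per sequence ID so the probes fit
    the promoter span.

    Returns ``(ArrayDesign, annotation)``; annotation columns are
    ``gene, chrom, cds_start, cds_end, tss, strand``.
    """
    rng = config.rng(_STREAM_DESIGN)
    lo_p, hi_p = config.probes_per_id
    lo_l, hi_l = config.probe_length
    lo_g, hi_g = config.inter_probe_gap
    span = config.span_length
    n_intergenic = int(round(config.intergenic_fraction * config.n_seq_ids))
    intergenic = set(
        rng.choice(config.n_seq_ids, size=n_intergenic, replace=False).tolist()
    )

    probe_rows = []
    ann_rows = []
    for i in range(config.n_seq_ids):
        seq_id, gene = _seq_gene(i)
        chrom = _CHROMS[i % len(_CHROMS)]
        slab_start = (i // len(_CHROMS)) * _SLAB
        tss = slab_start + _SLAB // 2
        n_probes = int(rng.integers(lo_p, hi_p + 1))
        lengths = rng.integers(lo_l, hi_l + 1, size=n_probes)
        if n_probes > 1:
            gap_hi = min(hi_g, (span - hi_l) // (n_probes - 1))
            if gap_hi < lo_g:
                raise ValueError(
                    f"impossible geometry for {seq_id}: {n_probes} probes at "
                    f"minimum spacing {lo_g} bp exceed the {span} bp span"
                )
            gaps = rng.integers(lo_g, gap_hi + 1, size=n_probes - 1)
            rel_starts = np.concatenate([[0], np.cumsum(gaps)])
        else:
            rel_starts = np.array([0])
        used = int(rel_starts[-1] + lengths[-1])
        shift = int(rng.integers(0, span - used + 1))
        starts = tss + config.promoter_span[0] + shift + rel_starts
        for j, (s, ln) in enumerate(zip(starts, lengths)):
            probe_rows.append(
                (
                    chrom,
                    int(s),
                    int(s + ln),
                    f"{seq_id}_P{j:03d}",
                    seq_id,
                    "" if i in intergenic else gene,
                )
            )
        if i not in intergenic:
            cds_start = tss + 200
            cds_end = cds_start + int(rng.integers(2000, 8001))
            ann_rows.append((gene, chrom, cds_start, cds_end, tss, "+"))

    probes = pd.DataFrame(
        probe_rows,
        columns=["chrom", "start", "end", "probe_id", "seq_id", "gene_symbol"],
    )
    annotation = pd.DataFrame(
        ann_rows, columns=["gene", "chrom", "cds_start", "cds_end", "tss", "strand"]
    )
    return ArrayDesign(probes, promoter_span=config.promoter_span), annotation


def sample_truth(
    design: ArrayDesign, annotation: pd.DataFrame, config: SimulationConfig
) -> GroundTruth:
    """Draw the spiked sequence IDs (with their probe runs) and DE genes."""
    rng = config.rng(_STREAM_TRUTH)
    sizes = design.probes.groupby("seq_id").size().sort_index()
    seq_ids = sizes.index.to_numpy()
    n_bound = int(round(config.bound_fraction * len(seq_ids)))
    chosen = sorted(rng.choice(seq_ids, size=n_bound, replace=False).tolist())
    bound_rows = []
    for seq_id in chosen:
        n = int(sizes[seq_id])
        run = min(int(rng.integers(config.spike_probes[0], config.spike_probes[1] + 1)), n)
        start = int(rng.integers(0, n - run + 1))
        bound_rows.append((seq_id, start, run))
    genes = annotation["gene"].to_numpy()
    n_de = int(round(config.de_fraction * len(genes)))
    de_genes = sorted(rng.choice(genes, size=n_de, replace=False).tolist())
    signs = rng.choice([-1.0, 1.0], size=n_de)
    truth = GroundTruth(
        bound=pd.DataFrame(bound_rows, columns=["seq_id", "spike_start", "spike_len"]),
        de=pd.DataFrame({"gene": de_genes, "effect": signs * config.expr_effect}),
    )
    return truth


def generate_chip_signal(
    design: ArrayDesign, truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Per-probe log2 enrichment for each ChIP replicate.

    Unspiked probes draw from Normal(0, noise_sd_chip); probes inside a
    spiked run are shifted by ``chip_effect`` in every replicate.
    Replicates are independent.
    """
    unknown = truth.bound_seq_ids - set(design.probes["seq_id"])
    if unknown:
        raise ValueError(f"truth references unknown sequence IDs: {sorted(unknown)}")
    if (truth.bound["spike_len"] < WINDOW_SIZE).any():
        raise ValueError(f"spiked spans must cover >= {WINDOW_SIZE} probes")
    rng = config.rng(_STREAM_CHIP)
    probes = design.probes  # already sorted by (seq_id, start, probe_id)
    values = rng.normal(
        0.0, config.noise_sd_chip, size=(len(probes), config.n_replicates_chip)
    )
    # first probe row per seq_id (probes are sorted, so min index)
    first_row = probes.reset_index().groupby("seq_id")["index"].min().to_dict()
    for rec in truth.bound.itertuples():
        base = first_row[rec.seq_id]
        values[base + rec.spike_start : base + rec.spike_start + rec.spike_len, :] += (
            config.chip_effect
        )
    return pd.DataFrame(
        values,
        index=pd.Index(probes["probe_id"], name="probe_id"),
        columns=[f"rep{r + 1}" for r in range(config.n_replicates_chip)],
    )


def generate_expression(
    annotation: pd.DataFrame, truth: GroundTruth, config: SimulationConfig
) -> ExpressionMatrix:
    """WT/KO log2 expression matrix with 1-3 probe sets per gene.

    Per probe set of gene g: WT samples ~ Normal(mu_g + delta_g, sd), KO
    samples ~ Normal(mu_g, sd), where delta_g is the true signed effect
    (0 for unspiked genes) and mu_g ~ Uniform(6, 10) is a gene baseline.
    With ``n_ambiguous > 0``, that many spiked multi-probe-set genes get one
    probe set with the opposite sign, to exercise the consistency filter
    downstream; they are recorded in ``truth.ambiguous``.
    """
    if config.n_wt < 2 or config.n_ko < 2:
        raise ValueError("need >= 2 WT and >= 2 KO samples for the t-test")
    genes = annotation["gene"].tolist()
    unknown = set(truth.de["gene"]) - set(genes)
    if unknown:
        raise ValueError(f"truth references unknown genes: {sorted(unknown)}")
    rng = config.rng(_STREAM_EXPR)
    effects = truth.de_genes
    lo_k, hi_k = config.probe_sets_per_gene
    samples = [f"WT{i + 1}" for i in range(config.n_wt)] + [
        f"KO{i + 1}" for i in range(config.n_ko)
    ]
    groups = pd.Series(
        ["WT"] * config.n_wt + ["KO"] * config.n_ko, index=samples, name="group"
    )
    n_sets = {g: int(rng.integers(lo_k, hi_k + 1)) for g in genes}
    ambiguous_pool = [g for g in genes if g in effects and n_sets[g] >= 2]
    if config.n_ambiguous > len(ambiguous_pool):
        raise ValueError(
            f"cannot inject {config.n_ambiguous} ambiguous genes: only "
            f"{len(ambiguous_pool)} spiked genes have >= 2 probe sets"
        )
    ambiguous = sorted(
        rng.choice(ambiguous_pool, size=config.n_ambiguous, replace=False).tolist()
    )
    rows = []
    index = []
    probe_map = {}
    for g in genes:
        mu = rng.uniform(6.0, 10.0)
        delta = effects.get(g, 0.0)
        for j in range(n_sets[g]):
            ps = f"{g}_ps{j + 1}"
            d = -delta if (g in ambiguous and j == 0) else delta
            wt = rng.normal(mu + d, config.noise_sd_expr, size=config.n_wt)
            ko = rng.normal(mu, config.noise_sd_expr, size=config.n_ko)
            rows.append(np.concatenate([wt, ko]))
            index.append(ps)
            probe_map[ps] = g
    values = pd.DataFrame(
        rows, index=pd.Index(index, name="probe_set"), columns=samples
    )
    truth.ambiguous = ambiguous
    return ExpressionMatrix(values, groups, pd.Series(probe_map, name="gene"))


def _concretize(consensus: str, rng: np.random.Generator) -> str:
    """Draw a concrete realisation of an IUPAC consensus."""
    out = []
    for c in consensus.upper():
        choices = sorted(IUPAC_CODES[c] - {"N"})
        out.append(choices[0] if len(choices) == 1 else rng.choice(choices))
    return "".join(out)


def plant_motifs(
    sequence: str,
    tss_index: int,
    plants,
    rng: np.random.Generator | None = None,
) -> tuple[str, list[tuple[str, int, str]]]:
    """Write motifs into a sequence at exact TSS-relative positions.

    ``plants`` is an iterable of ``(motif, position)`` where ``motif`` is a
    :class:`Motif` or raw consensus string and ``position`` the skip-zero
    TSS-relative position of the 5'-most base.  Ambiguous consensus
    positions are concretised with ``rng``.  Overlapping plants, or plants
    outside the sequence, are rejected.

    Returns the edited sequence and ``(name, position, strand)`` records.
    """
    rng = rng or np.random.default_rng(0)
    seq = list(sequence.upper())
    occupied: list[tuple[int, int]] = []
    records = []
    for motif, position in plants:
        if isinstance(motif, Motif):
            name, consensus = motif.name, motif.consensus
        else:
            name, consensus = str(motif), str(motif)
        site = _concretize(consensus, rng)
        start = position_to_offset(position, tss_index)
        end = start + len(site)
        if start < 0 or end > len(seq):
            raise ValueError(
                f"plant {name} at position {position} falls outside the sequence"
            )
        for s, e in occupied:
            if start < e and s < end:
                raise ValueError(
                    f"plant {name} at position {position} overlaps another plant"
                )
        occupied.append((start, end))
        seq[start:end] = site
        records.append((name, position, "+"))
    return "".join(seq), records


def generate_promoters(
    design: ArrayDesign,
    truth: GroundTruth,
    config: SimulationConfig,
    plants_by_seq=None,
    motif_table=DEFAULT_MOTIFS,
) -> dict[str, tuple[str, int]]:
    """Promoter sequences (one per sequence ID) with planted motifs.

    Background bases are i.i.d. uniform ACGT over the promoter span; the
    TSS index equals ``-promoter_span[0]``.  ``config.motif_plants`` (motif
    name, position) is applied to every promoter; ``plants_by_seq`` maps
    individual sequence IDs to extra plant lists and takes the same form.
    Motif names are resolved through ``motif_table``; unknown names are
    treated as raw consensus strings.  Planted records are appended to
    ``truth.planted``.
    """
    rng = config.rng(_STREAM_PROM)
    by_name = {m.name: m for m in motif_table}
    span = config.span_length
    tss_index = -config.promoter_span[0]
    plants_by_seq = plants_by_seq or {}
    promoters = {}
    planted_rows = []
    bases = np.array(list("ACGT"))
    for seq_id in design.seq_ids:
        background = "".join(bases[rng.integers(0, 4, size=span)])
        plants = [
            (by_name.get(name, name), pos)
            for name, pos in list(config.motif_plants) + list(plants_by_seq.get(seq_id, []))
        ]
        seq, records = plant_motifs(background, tss_index, plants, rng)
        promoters[seq_id] = (seq, tss_index)
        planted_rows.extend((seq_id, n, p, s) for n, p, s in records)
    if planted_rows:
        truth.planted = pd.concat(
            [
                truth.planted,
                pd.DataFrame(
                    planted_rows, columns=["seq_id", "motif", "position", "strand"]
                ),
            ],
            ignore_index=True,
        )
    return promoters


# --- Tal1-style promoter fixture -------------------------------------------
#
# The box map of the (newly mapped) mouse Tal1 promoter: three CACCC boxes
# at -788/-710/-185, two CCAAT boxes at -133/-57 and a TATA box at -28,
# all upstream of the TSS.  The fixture reproduces that map on a synthetic
# background scrubbed of any other core-box occurrence, so annotation is
# exact.

TAL1_BOX_MAP: tuple[tuple[str, int], ...] = (
    ("CACCC", -788),
    ("CACCC", -710),
    ("CACCC", -185),
    ("CCAAT", -133),
    ("CCAAT", -57),
    ("TATAA", -28),
)

# Mutated CACCC-box fragments of the Tal1 promoter (the CACCC core replaced
# by catat), used as negative controls for the scanner; E3_RESTORED is the
# E3 fragment with the box restored.
TAL1_MUT_E1 = "CAGGCAAAACCAGGGACCACATATTTAAAAATGATTCCCCTTCTCAAG"
TAL1_MUT_E2 = "CAATAGCTCTTCAGTTAGCGGTGAAGGCTCATGAACATATCCAC"
TAL1_MUT_E3 = "GAGTTATTGACACAGCCCTGTCATATCCTCCCCCCACTG"
TAL1_E3_RESTORED = "GAGTTATTGACACAGCCCTGTCACCCCCTCCCCCCACTG"

_FORBIDDEN = tuple(
    {p for pats in (("CACCC",), ("CCAAT", "ATTGG"), ("TATAA",)) for p in pats}
    | {reverse_complement(p) for p in ("CACCC", "CCAAT", "TATAA", "ATTGG")}
)


def tal1_like_promoter(seed: int = 0, length: int = 1000, tss_index: int = 900):
    """Synthetic promoter carrying the Tal1 box map, exactly.

    Returns ``(sequence, tss_index)`` covering positions
    ``-tss_index .. +(length - tss_index)``.  The background contains no
    CACCC/CCAAT/TATAA occurrence (either orientation) other than the six
    planted boxes, so :func:`promtarget.motifs.annotate_promoter` recovers
    the map with no extras.
    """
    rng = np.random.default_rng([seed, 97])
    bases = np.array(list("ACGT"))
    background = "".join(bases[rng.integers(0, 4, size=length)])
    seq, _ = plant_motifs(background, tss_index, TAL1_BOX_MAP, rng)
    planted = {
        (position_to_offset(pos, tss_index), len(site))
        for site, pos in TAL1_BOX_MAP
    }

    def violations(s: str):
        hits = []
        for pat in _FORBIDDEN:
            for i in range(len(s) - len(pat) + 1):
                if s[i : i + len(pat)] == pat and (i, len(pat)) not in planted:
                    hits.append((i, len(pat)))
        return hits

    seq_list = list(seq)
    protected = {
        i for start, ln in planted for i in range(start, start + ln)
    }
    for _ in range(1000):
        hits = violations("".join(seq_list))
        if not hits:
            break
        for start, ln in hits:
            editable = [i for i in range(start, start + ln) if i not in protected]
            i = int(rng.choice(editable))
            seq_list[i] = rng.choice([b for b in "ACGT" if b != seq_list[i]])
    else:  # pragma: no cover - practically unreachable
        raise RuntimeError("could not scrub fixture background")
    return "".join(seq_list), tss_index
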