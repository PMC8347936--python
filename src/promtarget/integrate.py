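"""Integration of binding calls with differential expression into target lists.

A gene is a candidate direct target when both evidence streams agree: at
least one of its probe sets is differentially expressed *and* at least one
sequence ID assigned to it is called bound.  Candidates are then filtered
on effect sizes -- binding effect (max window mean, log2) strictly above
``chip_threshold`` and absolute expression effect (log2 WT - KO) strictly
above ``expr_threshold`` -- and split by the expression-effect sign into
genes activated by the factor (higher in WT) and genes repressed by it
(higher in KO).

The module also provides generic set-overlap reporting and a right-tailed
hypergeometric (Fisher) enrichment test for user-supplied category sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CHIP_EFFECT_THRESHOLD = 0.25
EXPR_EFFECT_THRESHOLD = 0.5

MATCH_COLUMNS = [
    "gene",
    "chip_effect",
    "expr_effect",
    "seq_ids",
    "probe_sets",
    "n_pairs",
]


def percent(count: float, denominator: float, digits: int = 1) -> float:
    """``100 * count / denominator`` rounded half-up to ``digits`` decimals."""
    if denominator == 0:
        raise ValueError("denominator must be nonzero")
    raw = Decimal(100) * Decimal(str(count)) / Decimal(str(denominator))
    q = Decimal(1).scaleb(-digits)
    return float(raw.quantize(q, rounding=ROUND_HALF_UP))


def match_platforms(
    gene_table: pd.DataFrame,
    bound_calls: pd.DataFrame,
    gene_assignment: pd.DataFrame,
) -> tuple[pd.DataFrame, int]:
    """Match DE genes with bound sequence IDs by gene symbol.

    Parameters
    ----------
    gene_table : DataFrame
        Gene-indexed expression calls (from
        :func:`promtarget.expression.call_differential`) with columns
        ``de, effect, de_probe_sets``.
    bound_calls : DataFrame
        Per-sequence-ID calls with columns ``seq_id, bound, effect_size``.
    gene_assignment : DataFrame
        ``seq_id, genes`` (semicolon-joined symbols) from
        :func:`promtarget.peaks.assign_genes_all`.

    Returns
    -------
    (matched, n_pairs)
        One row per gene with >= 1 DE probe set and >= 1 bound sequence ID;
        ``chip_effect`` is the maximum binding effect over its bound
        sequence IDs.  ``n_pairs`` is the total number of matched
        (sequence ID, probe set) pairs across all matched genes.  Symbols
        are matched exactly after whitespace trimming; empty symbols never
        match.
    """
    assignment = gene_assignment.assign(
        gene=gene_assignment["genes"].str.split(";")
    ).explode("gene")
    assignment["gene"] = assignment["gene"].fillna("").str.strip()
    n_empty = int((assignment["gene"] == "").sum())
    if n_empty:
        logger.info("%d sequence-ID assignments without a symbol skipped", n_empty)
    assignment = assignment[assignment["gene"] != ""]

    bound = bound_calls[bound_calls["bound"]][["seq_id", "effect_size"]]
    bound_genes = assignment.merge(bound, on="seq_id")

    de = gene_table[gene_table["de"]].copy()
    de.index = de.index.astype(str).str.strip()
    de = de[de.index != ""]

    rows = []
    n_pairs = 0
    for gene, grp in bound_genes.groupby("gene", sort=True):
        if gene not in de.index:
            continue
        seq_ids = sorted(grp["seq_id"].unique())
        probe_sets = [p for p in str(de.loc[gene, "de_probe_sets"]).split(";") if p]
        pairs = len(seq_ids) * len(probe_sets)
        n_pairs += pairs
        rows.append(
            (
                gene,
                float(grp["effect_size"].max()),
                float(de.loc[gene, "effect"]),
                ";".join(seq_ids),
                ";".join(probe_sets),
                pairs,
            )
        )
    return pd.DataFrame(rows, columns=MATCH_COLUMNS), n_pairs


ACTIVATED = "activated"  # higher in WT: the factor activates the gene
REPRESSED = "repressed"  # higher in KO: the factor represses the gene


def filter_targets(
    matched: pd.DataFrame,
    chip_threshold: float = CHIP_EFFECT_THRESHOLD,
    expr_threshold: float = EXPR_EFFECT_THRESHOLD,
) -> pd.DataFrame:
    """Apply the strict effect-size filters and classify targets.

    Keeps rows with ``chip_effect > chip_threshold`` and
    ``|expr_effect| > expr_threshold`` (strict inequalities; a record
    exactly at a threshold is excluded).  Adds a ``regulation`` column:
    ``activated`` for positive expression effects, ``repressed`` for
    negative.  Rows with missing effect sizes are excluded and logged.
    """
    ok = matched["chip_effect"].notna() & matched["expr_effect"].notna()
    if (~ok).any():
        logger.warning("%d matched records missing an effect size", int((~ok).sum()))
    m = matched[ok]
    keep = (m["chip_effect"] > chip_threshold) & (
        m["expr_effect"].abs() > expr_threshold
    )
    out = m[keep].copy()
    out["regulation"] = [
        ACTIVATED if e > 0 else REPRESSED for e in out["expr_effect"]
    ]
    return out.reset_index(drop=True)


@dataclass
class OverlapReport:
    """Pairwise/triple intersections of up to three symbol sets."""

    sizes: dict[str, int]
    intersections: dict[str, int]
    denominator: int
    percentages: dict[str, float]
    raw_percentages: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [("size:" + k, v, None, None) for k, v in self.sizes.items()]
        rows += [
            (k, v, self.percentages[k], self.raw_percentages[k])
            for k, v in self.intersections.items()
        ]
        return pd.DataFrame(rows, columns=["set", "count", "percent", "percent_raw"])


def overlap_stats(
    set_a, set_b, set_c=None, denominator: int | None = None
) -> OverlapReport:
    """Exact intersection counts and percentages for two or three sets.

    Percentages use ``denominator`` (default: ``|A|``) and are reported
    both rounded half-up to one decimal and raw.
    """
    a, b = set(set_a), set(set_b)
    c = set(set_c) if set_c is not None else None
    denominator = len(a) if denominator is None else denominator
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    sizes = {"A": len(a), "B": len(b)}
    inter = {"A&B": len(a & b)}
    if c is not None:
        sizes["C"] = len(c)
        inter.update(
            {"A&C": len(a & c), "B&C": len(b & c), "A&B&C": len(a & b & c)}
        )
        union = len(a) + len(b) + len(c) - inter["A&B"] - inter["A&C"] - inter[
            "B&C"
        ] + inter["A&B&C"]
    else:
        union = len(a) + len(b) - inter["A&B"]
    inter["union"] = union
    return OverlapReport(
        sizes=sizes,
        intersections=inter,
        denominator=denominator,
        percentages={k: percent(v, denominator) for k, v in inter.items()},
        raw_percentages={k: 100.0 * v / denominator for k, v in inter.items()},
    )


def fisher_enrichment(
    target_set, category_sets, universe
) -> pd.DataFrame:
    """Right-tailed Fisher (upper hypergeometric tail) per category.

    For each category C: with population ``N = |universe|``, ``K = |C|``
    successes and ``n = |targets|`` draws, the p-value is
    ``P(X >= observed overlap)`` under the hypergeometric law -- the
    probability that an overlap at least as large arises by chance.

    Returns a frame sorted by p-value with columns
    ``category, category_size, overlap, p``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    targets = set(target_set)
    if not targets <= universe:
        raise ValueError("target set must be a subset of the universe")
    rows = []
    for name, members in category_sets.items():
        members = set(members)
        if not members <= universe:
            raise ValueError(f"category {name!r} is not a subset of the universe")
        k = len(targets & members)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(members), len(targets)))
        rows.append((name, len(members), k, p))
    out = pd.DataFrame(rows, columns=["category", "category_size", "overlap", "p"])
    return out.sort_values(["p", "category"], kind="stable").reset_index(drop=True)
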