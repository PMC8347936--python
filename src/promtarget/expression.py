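"""Differential expression between wild-type and knockout replicate groups.

Probe sets are compared with a two-sided, pooled-variance two-sample t-test
on log2 expression values.  The signed effect size of a probe set is
``mean(WT) - mean(KO)`` on the log2 scale, so a positive effect means the
gene is higher in the wild type (activated by the factor under study).

Gene-level calls add two rules on top of the probe-set test:

* consistency filter -- a gene whose *significant* probe sets disagree in
  sign is removed as ambiguous (single-probe-set genes are trivially
  consistent);
* a retained gene is differentially expressed when at least one of its
  probe sets is significant; its effect size is the mean of the significant
  probe-set effects and its direction the sign of that mean.

No multiple-testing correction is applied across probe sets: the pipeline
filters at the raw per-probe-set level and controls false positives later
by intersecting with the independent binding evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DE_ALPHA = 0.05
GROUPS = ("WT", "KO")


@dataclass
class ExpressionMatrix:
    """Log2 expression values with group labels and a probe-set->gene map.

    ``values``: probe_set x sample frame; ``groups``: sample -> "WT"/"KO";
    ``probe_map``: probe_set -> gene symbol (empty string = unmapped).
    Rows with missing values are dropped (and logged) at construction.
    """

    values: pd.DataFrame
    groups: pd.Series
    probe_map: pd.Series

    def __post_init__(self) -> None:
        unknown = set(self.groups.unique()) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels {sorted(unknown)}")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")
        for g in GROUPS:
            if (self.groups.loc[list(self.values.columns)] == g).sum() < 2:
                raise ValueError(f"group {g} needs >= 2 samples")
        n_bad = int(self.values.isna().any(axis=1).sum())
        if n_bad:
            logger.warning("dropping %d probe sets with missing values", n_bad)
            self.values = self.values.dropna()
        self.probe_map = self.probe_map.reindex(self.values.index, fill_value="")
        self.probe_map = self.probe_map.fillna("").astype(str).str.strip()

    def group_columns(self, group: str) -> list[str]:
        return [c for c in self.values.columns if self.groups[c] == group]

    def swap_groups(self) -> "ExpressionMatrix":
        """Relabel WT as KO and vice versa (sign-symmetry checks)."""
        swapped = self.groups.map({"WT": "KO", "KO": "WT"})
        return ExpressionMatrix(self.values.copy(), swapped, self.probe_map.copy())


def probe_set_ttest(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Pooled-variance two-sample t-test for every probe set.

    Returns a probe_set-indexed frame with columns ``t, p, effect,
    degenerate``; ``effect = mean(WT) - mean(KO)`` (log2).  Zero pooled
    variance with zero mean difference gives t = 0, p = 1; with a nonzero
    difference it gives p = 0 and sets the ``degenerate`` flag.
    """
    wt = matrix.values[matrix.group_columns("WT")].to_numpy(float)
    ko = matrix.values[matrix.group_columns("KO")].to_numpy(float)
    if not (np.isfinite(wt).all() and np.isfinite(ko).all()):
        raise ValueError("expression values must be finite")
    n1, n2 = wt.shape[1], ko.shape[1]
    diff = wt.mean(axis=1) - ko.mean(axis=1)
    pooled = (
        (n1 - 1) * wt.var(axis=1, ddof=1) + (n2 - 1) * ko.var(axis=1, ddof=1)
    ) / (n1 + n2 - 2)
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    degenerate = (se == 0.0) & (diff != 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0.0, diff / np.where(se > 0.0, se, 1.0), 0.0)
    t = np.where(degenerate, np.where(diff > 0, np.inf, -np.inf), t)
    p = 2.0 * stats.t.sf(np.abs(t), df=n1 + n2 - 2)
    p = np.where(degenerate, 0.0, p)
    p = np.where((se == 0.0) & (diff == 0.0), 1.0, p)
    return pd.DataFrame(
        {"t": t, "p": p, "effect": diff, "degenerate": degenerate},
        index=matrix.values.index.rename("probe_set"),
    )


def consistency_filter(
    probe_results: pd.DataFrame, probe_map: pd.Series, alpha: float = DE_ALPHA
) -> pd.DataFrame:
    """Flag genes whose significant probe sets disagree in effect sign.

    A gene is removed iff it has two or more significant probe sets
    (two-sided p < alpha) whose effects carry both signs.  Genes with a
    single probe set, or no significant probe set, are retained.  Probe
    sets with an empty gene mapping are ignored (logged).

    Returns a gene-indexed frame: ``n_probe_sets, n_significant, retained,
    reason`` (empty string, or "ambiguous").
    """
    mapped = probe_map.reindex(probe_results.index).fillna("")
    n_unmapped = int((mapped == "").sum())
    if n_unmapped:
        logger.info("%d probe sets without a gene symbol ignored", n_unmapped)
    res = probe_results.loc[mapped != ""].copy()
    res["gene"] = mapped[mapped != ""]
    rows = []
    for gene, grp in res.groupby("gene", sort=True):
        sig = grp[grp["p"] < alpha]
        signs = set(np.sign(sig["effect"]).astype(int)) - {0}
        ambiguous = len(grp) > 1 and len(signs) > 1
        rows.append(
            (gene, len(grp), len(sig), not ambiguous, "ambiguous" if ambiguous else "")
        )
    out = pd.DataFrame(
        rows, columns=["gene", "n_probe_sets", "n_significant", "retained", "reason"]
    )
    return out.set_index("gene")


def call_differential(
    probe_results: pd.DataFrame,
    probe_map: pd.Series,
    alpha: float = DE_ALPHA,
    consistency: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Gene-level differential-expression calls after the consistency filter.

    A retained gene is DE iff >= 1 of its probe sets has p < alpha; its
    effect size is the mean of its significant probe-set effects and its
    direction the sign of that mean (0 for non-DE genes).  Removed genes
    appear with ``retained = False`` and no call.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if consistency is None:
        consistency = consistency_filter(probe_results, probe_map, alpha)
    mapped = probe_map.reindex(probe_results.index).fillna("")
    res = probe_results.loc[mapped != ""].copy()
    res["gene"] = mapped[mapped != ""]
    rows = []
    for gene, grp in res.groupby("gene", sort=True):
        retained = bool(consistency.loc[gene, "retained"])
        sig = grp[grp["p"] < alpha]
        de = retained and len(sig) > 0
        effect = float(sig["effect"].mean()) if de else float("nan")
        direction = int(np.sign(effect)) if de else 0
        rows.append(
            (
                gene,
                retained,
                de,
                effect,
                direction,
                len(sig),
                ";".join(sorted(sig.index)),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "retained",
            "de",
            "effect",
            "direction",
            "n_significant",
            "de_probe_sets",
        ],
    ).set_index("gene")


@dataclass
class DEResult:
    """Bundle of probe-set and gene-level differential-expression tables."""

    probe_table: pd.DataFrame
    gene_table: pd.DataFrame
    alpha: float

    @property
    def n_significant_probe_sets(self) -> int:
        return int((self.probe_table["p"] < self.alpha).sum())

    @property
    def removed_genes(self) -> list[str]:
        return sorted(self.gene_table.index[~self.gene_table["retained"]])

    @property
    def de_genes(self) -> pd.DataFrame:
        return self.gene_table[self.gene_table["de"]]


def profile_expression(matrix: ExpressionMatrix, alpha: float = DE_ALPHA) -> DEResult:
    """Full expression stage: probe-set tests, consistency filter, gene calls."""
    probe_table = probe_set_ttest(matrix)
    consistency = consistency_filter(probe_table, matrix.probe_map, alpha)
    gene_table = call_differential(probe_table, matrix.probe_map, alpha, consistency)
    return DEResult(probe_table, gene_table, alpha)
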