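"""Moving-window binding calls on promoter tiling-array enrichment data.

A promoter array groups neighbouring probes into "sequence IDs", each
covering roughly -3.75 kb..+0.75 kb around a transcription start site.  For
every sequence ID a window of ``w = 5`` consecutive probes slides one probe
at a time; each window's mean log2 enrichment is tested against zero with a
one-sample, one-sided t-test (df = w - 1).  A sequence ID is called bound
when at least one window is significant at the per-window level ``alpha``
(default 0.0017, chosen so that the family-wise error over the windows of a
typical sequence ID is about 0.05).  The sequence-ID effect size is the
maximum window mean on the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

WINDOW_SIZE = 5
WINDOW_ALPHA = 0.0017
GENE_FLANK = 10_000

WINDOW_COLUMNS = ["window_index", "mean", "t", "p", "significant", "degenerate"]


def adjusted_alpha(per_window_alpha: float, n_windows: int) -> float:
    """Family-wise significance level ``1 - (1 - alpha)**n`` for n windows.

    This is the probability of at least one significant window among
    ``n_windows`` independent null windows; overlapping windows are
    positively correlated, so for a real sequence ID it is conservative.

    >>> round(adjusted_alpha(0.0017, 30), 4)
    0.0497
    """
    if not 0.0 < per_window_alpha < 1.0:
        raise ValueError("per-window alpha must lie strictly between 0 and 1")
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    return 1.0 - (1.0 - per_window_alpha) ** n_windows


def moving_window_test(
    values, w: int = WINDOW_SIZE, alpha: float = WINDOW_ALPHA
) -> pd.DataFrame:
    """One-sided one-sample t-test on every w-probe window of one sequence ID.

    Parameters
    ----------
    values : array-like
        Per-probe mean log2 enrichment, ordered along the promoter.
    w : int
        Window size in probes (default 5).
    alpha : float
        Per-window significance level (default 0.0017).

    Returns
    -------
    DataFrame with one row per window (``n - w + 1`` rows; empty when
    ``n < w``): window index (offset of the first probe), window mean,
    t statistic, upper-tail p-value, significance flag, and a ``degenerate``
    flag for zero-variance windows, where significance reduces to the sign
    of the mean (t -> +/-inf).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    if w < 2:
        raise ValueError("window size must be >= 2")
    if x.size < w:
        return pd.DataFrame(columns=WINDOW_COLUMNS).astype(
            {"window_index": int, "significant": bool, "degenerate": bool}
        )
    windows = sliding_window_view(x, w)
    mean = windows.mean(axis=1)
    sd = windows.std(axis=1, ddof=1)
    degenerate = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, np.sign(mean) * np.inf, mean / (sd / np.sqrt(w)))
    t = np.where(degenerate & (mean == 0.0), 0.0, t)
    p = stats.t.sf(t, df=w - 1)
    # all-equal windows: significant iff the (exactly known) mean is positive
    p = np.where(degenerate, np.where(mean > 0.0, 0.0, 1.0), p)
    return pd.DataFrame(
        {
            "window_index": np.arange(mean.size),
            "mean": mean,
            "t": t,
            "p": p,
            "significant": p < alpha,
            "degenerate": degenerate,
        }
    )


@dataclass
class BoundCall:
    """Sequence-ID level summary of the moving-window test."""

    seq_id: str
    bound: bool
    effect_size: float  # max window mean (log2); NaN when untestable
    best_window: int | None
    n_windows: int
    status: str = "ok"  # "ok" or "untestable" (< w probes)


def call_bound(
    windows: pd.DataFrame, seq_id: str = "", untestable: bool = False
) -> BoundCall:
    """Summarise one sequence ID: bound iff any window is significant.

    The effect size is the maximum window mean across *all* windows; the
    best window is the significant window with the largest mean when bound,
    otherwise the overall-largest window.
    """
    if untestable or windows.empty:
        return BoundCall(seq_id, False, float("nan"), None, 0, "untestable")
    bound = bool(windows["significant"].any())
    effect = float(windows["mean"].max())
    pool = windows[windows["significant"]] if bound else windows
    best = int(pool.loc[pool["mean"].idxmax(), "window_index"])
    return BoundCall(seq_id, bound, effect, best, len(windows))


@dataclass
class ArrayDesign:
    """Probe table of a promoter tiling array.

    ``probes`` columns: chrom, start, end (0-based half-open), probe_id,
    seq_id, gene_symbol (may be empty).  Probes are kept sorted by genomic
    start within each sequence ID, ties broken by probe id.
    """

    probes: pd.DataFrame
    promoter_span: tuple[int, int] = (-3750, 750)
    _order: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "probe_id", "seq_id"}
        missing = required - set(self.probes.columns)
        if missing:
            raise ValueError(f"design is missing columns {sorted(missing)}")
        if (self.probes["end"] <= self.probes["start"]).any():
            raise ValueError("malformed probe intervals (end <= start)")
        self.probes = self.probes.sort_values(
            ["seq_id", "start", "probe_id"], kind="stable"
        ).reset_index(drop=True)

    @property
    def seq_ids(self) -> list[str]:
        return sorted(self.probes["seq_id"].unique())

    def probes_of(self, seq_id: str) -> pd.DataFrame:
        return self.probes[self.probes["seq_id"] == seq_id]

    def seq_intervals(self) -> pd.DataFrame:
        """Per sequence ID: chrom, start (min probe start), end (max end)."""
        g = self.probes.groupby("seq_id")
        out = g.agg(
            chrom=("chrom", "first"), start=("start", "min"), end=("end", "max"),
            n_probes=("probe_id", "size"),
        )
        return out.reset_index()


def probe_values(signal: pd.DataFrame) -> pd.Series:
    """Per-probe analysis value: mean log2 enrichment across replicates."""
    return signal.mean(axis=1)


def call_bound_all(
    design: ArrayDesign,
    signal: pd.DataFrame,
    w: int = WINDOW_SIZE,
    alpha: float = WINDOW_ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the moving-window test over every sequence ID of a design.

    ``signal`` is a probe_id-indexed frame with one column per ChIP
    replicate; replicates are averaged per probe before testing.

    Returns ``(windows, calls)``: the concatenated window-level table and a
    per-sequence-ID table with columns ``seq_id, bound, effect_size,
    best_window, n_windows, status``.
    """
    values = probe_values(signal)
    missing = set(design.probes["probe_id"]) - set(values.index)
    if missing:
        raise ValueError(f"{len(missing)} design probes missing from signal")
    window_frames = []
    calls = []
    for seq_id, grp in design.probes.groupby("seq_id", sort=True):
        x = values.loc[grp["probe_id"]].to_numpy()
        wins = moving_window_test(x, w=w, alpha=alpha)
        call = call_bound(wins, seq_id=seq_id, untestable=x.size < w)
        calls.append(call)
        if not wins.empty:
            wins = wins.assign(seq_id=seq_id)
            window_frames.append(wins)
    windows = (
        pd.concat(window_frames, ignore_index=True)[["seq_id"] + WINDOW_COLUMNS]
        if window_frames
        else pd.DataFrame(columns=["seq_id"] + WINDOW_COLUMNS)
    )
    calls_df = pd.DataFrame([vars(c) for c in calls])
    return windows, calls_df


def assign_genes(
    seq_start: int, seq_end: int, annotation: pd.DataFrame, flank: int = GENE_FLANK,
    chrom: str | None = None,
) -> list[str]:
    """Genes whose coding interval intersects the flanked sequence-ID region.

    The region is ``[seq_start - flank, seq_end + flank)``; an empty result
    marks the sequence ID as intergenic.
    """
    ann = annotation
    if chrom is not None:
        ann = ann[ann["chrom"] == chrom]
    _check_annotation(annotation)
    hit = (ann["cds_start"] < seq_end + flank) & (ann["cds_end"] > seq_start - flank)
    return sorted(ann.loc[hit, "gene"].tolist())


def _check_annotation(annotation: pd.DataFrame) -> None:
    required = {"gene", "chrom", "cds_start", "cds_end"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation is missing columns {sorted(missing)}")
    if (annotation["cds_end"] <= annotation["cds_start"]).any():
        raise ValueError("malformed coding intervals (cds_end <= cds_start)")


def assign_genes_all(
    design: ArrayDesign, annotation: pd.DataFrame, flank: int = GENE_FLANK
) -> pd.DataFrame:
    """Per sequence ID, the genes within ``flank`` of its probe span.

    Returns columns ``seq_id, genes`` (semicolon-joined, empty string when
    intergenic) and ``intergenic``.
    """
    _check_annotation(annotation)
    intervals = design.seq_intervals()
    rows = []
    by_chrom = {c: g for c, g in annotation.groupby("chrom")}
    for rec in intervals.itertuples():
        ann = by_chrom.get(rec.chrom)
        if ann is None:
            genes: list[str] = []
        else:
            hit = (ann["cds_start"] < rec.end + flank) & (
                ann["cds_end"] > rec.start - flank
            )
            genes = sorted(ann.loc[hit, "gene"].tolist())
        rows.append((rec.seq_id, ";".join(genes), not genes))
    return pd.DataFrame(rows, columns=["seq_id", "genes", "intergenic"])
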