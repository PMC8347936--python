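"""Consensus motif scanning and co-occurrence analysis on promoter sequences.

Transcription-factor binding elements are represented as IUPAC consensus
strings (e.g. the KLF-family CACCC box, the GATA box ``WGATAR``) and matched
exactly -- no mismatches, no position-weight scores.  Occurrence positions are
reported relative to the transcription start site (TSS) using the classical
promoter convention: upstream positions are negative, downstream positive,
and there is no position 0 (``-1`` abuts ``+1``).

The co-occurrence statistics follow the promoter-array style of analysis:
each promoter ("sequence ID") contributes at most one representative signed
distance between a reference motif (typically the CACCC/KLF box) and a
partner motif -- the pair with the smallest absolute separation.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: IUPAC nucleotide codes mapped to the set of concrete bases they accept.
#: A literal ``N`` in the scanned sequence (an unknown base) matches only a
#: consensus ``N``, never a constrained position.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGTN"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

SEQUENCE_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class Motif:
    """A named IUPAC consensus, e.g. ``Motif("GATA", "WGATAR")``."""

    name: str
    consensus: str

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"motif {self.name!r}: empty consensus")
        bad = set(self.consensus.upper()) - set(IUPAC_CODES)
        if bad:
            raise ValueError(
                f"motif {self.name!r}: non-IUPAC characters {sorted(bad)}"
            )
        object.__setattr__(self, "consensus", self.consensus.upper())

    def __len__(self) -> int:
        return len(self.consensus)


#: Default motif table.  The KLF/EKLF box is the core CACCC element; the
#: extended canonical zinc-finger site CCNCNCCC is carried as a separate
#: entry rather than merged into it.
DEFAULT_MOTIFS: tuple[Motif, ...] = (
    Motif("EKLF", "CACCC"),
    Motif("EKLF_extended", "CCNCNCCC"),
    Motif("GATA", "WGATAR"),
    Motif("TAL1", "CANNTG"),
    Motif("CCAAT", "CCAAT"),
    Motif("TATA", "TATAA"),
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide or IUPAC consensus string."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def tss_relative_position(offset: int, tss_index: int) -> int:
    """Convert a 0-based sequence offset to a skip-zero TSS coordinate.

    ``tss_index`` is the 0-based offset of the base at position +1.  The
    base immediately upstream (offset ``tss_index - 1``) is position -1.
    """
    return offset - tss_index if offset < tss_index else offset - tss_index + 1


def position_to_offset(position: int, tss_index: int) -> int:
    """Inverse of :func:`tss_relative_position`; rejects position 0."""
    if position == 0:
        raise ValueError("TSS-relative coordinates have no position 0")
    return tss_index + position if position < 0 else tss_index + position - 1


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - SEQUENCE_ALPHABET
    if bad:
        raise ValueError(f"invalid sequence characters: {sorted(bad)}")
    return seq


def _matches_at(seq: str, consensus: str, offset: int) -> bool:
    return all(
        seq[offset + j] in IUPAC_CODES[consensus[j]]
        for j in range(len(consensus))
    )


OCCURRENCE_COLUMNS = ["seq_id", "motif", "start", "position", "strand", "match"]


def scan_motifs(
    sequence: str,
    motifs,
    both_strands: bool = True,
    tss_index: int | None = None,
    seq_id: str = "",
) -> pd.DataFrame:
    """Report every exact IUPAC match of each motif in ``sequence``.

    Parameters
    ----------
    sequence : str
        Promoter sequence over ``{A, C, G, T, N}`` (case-insensitive).
    motifs : iterable of Motif
        Consensus motifs to scan for.
    both_strands : bool
        When true (default) the reverse complement of each consensus is also
        scanned; hits are still reported by the forward-strand offset of
        their 5'-most base, with ``strand`` set to ``-``.
    tss_index : int, optional
        0-based offset of the TSS (+1) base; when given, the ``position``
        column carries skip-zero TSS-relative coordinates.
    seq_id : str
        Identifier copied into the output.

    Returns
    -------
    DataFrame with columns ``seq_id, motif, start, position, strand, match``,
    sorted by start offset.  Overlapping matches are all reported.
    """
    seq = _validate_sequence(sequence)
    rows = []
    for motif in motifs:
        patterns = [(motif.consensus, "+")]
        if both_strands:
            rc = reverse_complement(motif.consensus)
            if rc != motif.consensus:
                patterns.append((rc, "-"))
            else:  # palindromic consensus: one strand suffices
                pass
        for pattern, strand in patterns:
            for i in range(len(seq) - len(pattern) + 1):
                if _matches_at(seq, pattern, i):
                    rows.append(
                        (
                            seq_id,
                            motif.name,
                            i,
                            tss_relative_position(i, tss_index)
                            if tss_index is not None
                            else pd.NA,
                            strand,
                            seq[i : i + len(pattern)],
                        )
                    )
    out = pd.DataFrame(rows, columns=OCCURRENCE_COLUMNS)
    return out.sort_values(["start", "motif", "strand"], kind="stable").reset_index(
        drop=True
    )


def scan_promoters(promoters, motifs, both_strands: bool = True) -> pd.DataFrame:
    """Scan a mapping ``seq_id -> (sequence, tss_index)`` with every motif."""
    frames = [
        scan_motifs(seq, motifs, both_strands, tss_index, seq_id)
        for seq_id, (seq, tss_index) in promoters.items()
    ]
    if not frames:
        return pd.DataFrame(columns=OCCURRENCE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def motif_frequency(occurrences: pd.DataFrame, motifs=None) -> pd.DataFrame:
    """Rank motifs by the number of sequence IDs in which they occur.

    Returns one row per motif with ``total_hits`` (all occurrences) and
    ``n_seq_ids`` (sequences with at least one hit), ranked by descending
    presence, ties broken by descending total hits and then by name.  When
    ``motifs`` is given, motifs without any occurrence are listed with zero
    counts (and hence rank last).
    """
    if occurrences.empty:
        grouped = pd.DataFrame(columns=["motif", "total_hits", "n_seq_ids"])
    else:
        grouped = (
            occurrences.groupby("motif")
            .agg(total_hits=("start", "size"), n_seq_ids=("seq_id", "nunique"))
            .reset_index()
        )
    if motifs is not None:
        absent = [m.name for m in motifs if m.name not in set(grouped["motif"])]
        if absent:
            zeros = pd.DataFrame(
                {"motif": absent, "total_hits": 0, "n_seq_ids": 0}
            )
            grouped = pd.concat([grouped, zeros], ignore_index=True)
    grouped = grouped.astype({"total_hits": int, "n_seq_ids": int}).sort_values(
        ["n_seq_ids", "total_hits", "motif"],
        ascending=[False, False, True],
        kind="stable",
    )
    grouped["rank"] = np.arange(1, len(grouped) + 1)
    return grouped.reset_index(drop=True)


def cooccurrence_distance(
    reference_occurrences: pd.DataFrame, partner_occurrences: pd.DataFrame
) -> pd.DataFrame:
    """Per sequence ID, the representative partner-to-reference distance.

    For every sequence ID containing both motifs, all (reference, partner)
    occurrence pairs compete and the signed distance
    ``partner_start - reference_start`` with the smallest absolute value is
    selected.  An exact tie between an upstream and a downstream candidate
    resolves to the upstream (negative) value.  Sequence IDs lacking either
    motif are skipped.

    Distances are computed on raw sequence offsets; they equal differences
    of TSS-relative positions except for pairs straddling the TSS, where the
    skip-zero convention would count one extra base.
    """
    out_rows = []
    ref_by_seq = dict(tuple(reference_occurrences.groupby("seq_id")))
    for seq_id, partners in partner_occurrences.groupby("seq_id"):
        refs = ref_by_seq.get(seq_id)
        if refs is None or refs.empty or partners.empty:
            continue
        d = (
            partners["start"].to_numpy()[:, None]
            - refs["start"].to_numpy()[None, :]
        ).ravel()
        order = np.lexsort((d, np.abs(d)))  # min |d|, then negative first
        out_rows.append((seq_id, int(d[order[0]])))
    return pd.DataFrame(out_rows, columns=["seq_id", "distance"])


Histogram = namedtuple("Histogram", ["bins", "out_of_range", "total"])


def distance_histogram(
    distances, bin_width: int = 50, limit: int = 1000
) -> Histogram:
    """Bin representative distances into fixed-width bins over ``±limit``.

    Bins are half-open ``[start, start + bin_width)``.  Records outside
    ``[-limit, limit)`` are tallied separately so that
    ``bins.count.sum() + out_of_range == total``.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    d = np.asarray(
        distances["distance"] if isinstance(distances, pd.DataFrame) else distances,
        dtype=float,
    )
    edges = np.arange(-limit, limit + bin_width, bin_width)
    in_range = (d >= -limit) & (d < limit)
    counts, _ = np.histogram(d[in_range], bins=edges)
    bins = pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )
    return Histogram(bins, int((~in_range).sum()), int(d.size))


#: Core-promoter boxes recognised by :func:`annotate_promoter`.  The CCAAT
#: box is accepted in either orientation on the forward strand (CCAAT or
#: ATTGG); the TATA box uses the TATAA consensus.
PROMOTER_BOXES: dict[str, tuple[str, ...]] = {
    "CACCC": ("CACCC",),
    "CCAAT": ("CCAAT", "ATTGG"),
    "TATA": ("TATAA",),
}


def annotate_promoter(sequence: str, tss_index: int) -> pd.DataFrame:
    """Locate CACCC, CCAAT and TATA boxes relative to the TSS.

    Scans the forward strand only and reports the skip-zero TSS-relative
    position of each box's 5'-most base.  Returns a DataFrame with columns
    ``box, position, match`` sorted by position.
    """
    seq = _validate_sequence(sequence)
    if not 0 <= tss_index <= len(seq):
        raise ValueError(
            f"tss_index {tss_index} outside sequence of length {len(seq)}"
        )
    rows = []
    for box, patterns in PROMOTER_BOXES.items():
        for pattern in patterns:
            for i in range(len(seq) - len(pattern) + 1):
                if _matches_at(seq, pattern, i):
                    rows.append(
                        (box, tss_relative_position(i, tss_index), seq[i : i + len(pattern)])
                    )
    out = pd.DataFrame(rows, columns=["box", "position", "match"])
    return out.sort_values(["position", "box"], kind="stable").reset_index(drop=True)
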