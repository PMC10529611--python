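"""Read merging, global alignment, HDR-marker gating and variant counting.

The calling rule mirrors how SGE amplicon data must be counted: a read
contributes to a library variant only when (i) it aligns to the amplicon
without indels, (ii) it carries every fixed synonymous marker edit (proof
the allele came from the HDR repair template, not from an unedited or
NHEJ-repaired chromosome), and (iii) all remaining substitutions fall
inside the saturated target region.  Reads with ``N`` bases are removed
before alignment; gapped reads are tallied into a per-(size, offset) indel
spectrum anchored at the Cas9 cut site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from sgekit.design import AmpliconDesign, VariantKey, variant_key_from_amplicon_edits
from sgekit.tables import WT_ROW, CountTable, indel_row, parse_indel_row

_VALID = set("ACGTN")


class FastqRead(NamedTuple):
    """Minimal FASTQ record: id, sequence, per-base Phred qualities."""

    id: str
    seq: str
    qual: tuple[int, ...]


# ---------------------------------------------------------------------------
# pair merging


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def merge_pairs(
    r1: Iterable[FastqRead],
    r2: Iterable[FastqRead],
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
) -> tuple[list[FastqRead], int]:
    """Overlap-merge mate pairs into single amplicon-spanning reads.

    For each pair the reverse mate is reverse-complemented and every
    overlap length ``>= min_overlap`` is scored; the overlap with the
    lowest mismatch fraction (ties: longest) wins.  Disagreeing overlap
    bases are resolved by the higher base quality.  Pairs with no
    admissible overlap are dropped and counted.

    Returns ``(merged reads, n_dropped)``.
    """
    merged: list[FastqRead] = []
    dropped = 0
    it2 = iter(r2)
    for a in r1:
        try:
            b = next(it2)
        except StopIteration:
            raise ValueError("unpaired mates: r2 exhausted before r1") from None
        if a.id.split("/")[0] != b.id.split("/")[0]:
            raise ValueError(f"unpaired mates: {a.id} vs {b.id}")
        bseq = _revcomp(b.seq)
        bqual = b.qual[::-1]
        best: tuple[float, int] | None = None
        max_o = min(len(a.seq), len(bseq))
        for o in range(max_o, min_overlap - 1, -1):
            tail = a.seq[len(a.seq) - o:]
            head = bseq[:o]
            mism = sum(1 for x, y in zip(tail, head) if x != y)
            frac = mism / o
            if frac <= max_mismatch_frac and (best is None or frac < best[0]):
                best = (frac, o)
        if best is None:
            dropped += 1
            continue
        o = best[1]
        left = len(a.seq) - o
        seq = list(a.seq[:left])
        qual = list(a.qual[:left])
        for k in range(o):
            x, qx = a.seq[left + k], a.qual[left + k]
            y, qy = bseq[k], bqual[k]
            if x == y:
                seq.append(x)
                qual.append(max(qx, qy))
            elif qy > qx:
                seq.append(y)
                qual.append(qy)
            else:
                seq.append(x)
                qual.append(qx)
        seq += list(bseq[o:])
        qual += list(bqual[o:])
        merged.append(FastqRead(a.id.split("/")[0], "".join(seq), tuple(qual)))
    if next(it2, None) is not None:
        raise ValueError("unpaired mates: r1 exhausted before r2")
    return merged, dropped


# ---------------------------------------------------------------------------
# Needleman-Wunsch global alignment


@dataclass(frozen=True)
class AlignScoring:
    """Linear-gap alignment scores.

    The default gap penalty is deliberately steep relative to a mismatch:
    a degenerate-codon (NNN) replacement of up to three adjacent bases
    must align as substitutions, never as a cheaper delete-plus-insert,
    or HDR-gated counting would misfile library variants as NHEJ indels.
    With match +2 / mismatch -1, any gap milder than about -5 lets a
    two-gap alignment beat three mismatches whenever it rescues a few
    matches; -6 keeps substitution alignments optimal for codon swaps
    while true length differences still force gaps.
    """

    match: int = 2
    mismatch: int = -1
    gap: int = -6  # linear gap penalty per base


@dataclass(frozen=True)
class Alignment:
    aligned_read: str
    aligned_ref: str
    score: int


def align_global(read: str, reference: str,
                 scoring: AlignScoring = AlignScoring()) -> Alignment:
    """Optimal global (Needleman-Wunsch) alignment under linear gap costs.

    Tie-breaking during traceback is deterministic: a diagonal move
    (match/mismatch) is preferred over gaps, and a gap in the read over a
    gap in the reference.  ``N`` scores as a mismatch against anything.
    See :class:`AlignScoring` for the default parameters and why the gap
    penalty is steep.
    """
    read, reference = read.upper(), reference.upper()
    if not read or not reference:
        raise ValueError("empty sequence")
    if set(read) - _VALID or set(reference) - _VALID:
        raise ValueError("sequences must be over ACGTN")
    n, m = len(read), len(reference)
    g = -scoring.gap  # positive cost
    ref_arr = np.frombuffer(reference.encode(), dtype=np.uint8)
    read_arr = np.frombuffer(read.encode(), dtype=np.uint8)
    n_code = ord("N")
    S = np.empty((n + 1, m + 1), dtype=np.int64)
    S[0, :] = -g * np.arange(m + 1)
    gj = g * np.arange(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        eq = (ref_arr == read_arr[i - 1]) & (ref_arr != n_code) & (read_arr[i - 1] != n_code)
        sub = np.where(eq, scoring.match, scoring.mismatch)
        diag = S[i - 1, :-1] + sub
        up = S[i - 1, 1:] - g
        cand = np.maximum(diag, up)
        # close left gaps within the row: row[j] = max(cand[j], row[j-1] - g)
        # unrolls to row[j] = max_{k<=j}(t[k] + g*k) - g*j with t[0] = S[i,0]
        t = np.empty(m + 1, dtype=np.int64)
        t[0] = -g * i
        t[1:] = cand
        S[i, :] = np.maximum.accumulate(t + gj) - gj
    # traceback with fixed move preference: diagonal, then gap-in-read
    # (consume reference), then gap-in-reference (consume read).
    out_read: list[str] = []
    out_ref: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            x, y = read[i - 1], reference[j - 1]
            sub = scoring.match if (x == y and x != "N") else scoring.mismatch
            if S[i, j] == S[i - 1, j - 1] + sub:
                out_read.append(x)
                out_ref.append(y)
                i, j = i - 1, j - 1
                continue
        if j > 0 and S[i, j] == S[i, j - 1] - g:
            out_read.append("-")
            out_ref.append(reference[j - 1])
            j -= 1
            continue
        out_read.append(read[i - 1])
        out_ref.append("-")
        i -= 1
    return Alignment("".join(out_read[::-1]), "".join(out_ref[::-1]),
                     int(S[n, m]))


# ---------------------------------------------------------------------------
# read classification


@dataclass(frozen=True)
class ReadClassification:
    """Outcome of the HDR-gating rule for one merged read."""

    category: str  # WT | HDR_variant | indel | rejected_N | rejected_other
    variant: VariantKey | None = None
    indel: tuple[int, int] | None = None  # (signed size, offset from cut)


def _alignment_ops(aln: Alignment):
    """Substitutions and indels in reference coordinates.

    Returns ``(subs, indels)`` where ``subs`` is a list of
    ``(ref_pos, ref_base, read_base)`` and ``indels`` a list of
    ``(ref_pos, signed size)`` with insertions positive.
    """
    subs: list[tuple[int, str, str]] = []
    indels: list[tuple[int, int]] = []
    ref_pos = 0
    k = 0
    a_read, a_ref = aln.aligned_read, aln.aligned_ref
    L = len(a_read)
    while k < L:
        x, y = a_read[k], a_ref[k]
        if x == "-":  # deletion from the read
            start = ref_pos
            size = 0
            while k < L and a_read[k] == "-":
                size += 1
                ref_pos += 1
                k += 1
            indels.append((start, -size))
        elif y == "-":  # insertion in the read
            start = ref_pos
            size = 0
            while k < L and a_ref[k] == "-":
                size += 1
                k += 1
            indels.append((start, size))
        else:
            if x != y:
                subs.append((ref_pos, y, x))
            ref_pos += 1
            k += 1
    return subs, indels


def _left_align_indel(pos: int, size: int, reference: str) -> int:
    """Shift an indel left while the local sequence is ambiguous."""
    if size < 0:  # deletion of reference[pos : pos - size]
        length = -size
        while pos > 0 and reference[pos - 1] == reference[pos + length - 1]:
            pos -= 1
    else:
        while pos > 0 and reference[pos - 1] == reference[pos]:
            pos -= 1
    return pos


def classify_read(aln: Alignment, design: AmpliconDesign) -> ReadClassification:
    """Apply the HDR-marker gating rule to one aligned read.

    Categories form a partition: ``rejected_N`` (read holds an N),
    ``indel`` (any alignment gap; recorded as the *net* signed size over
    all gap runs — net size is invariant to how the aligner splits an
    ambiguous indel and determines the reading frame — at the offset of
    the leftmost gap edge from the cut site, after left-alignment),
    ``HDR_variant`` (all marker edits present, every other substitution
    inside the target region), ``WT`` (zero differences), otherwise
    ``rejected_other``.
    """
    read_seq = aln.aligned_read.replace("-", "")
    if "N" in read_seq:
        return ReadClassification("rejected_N")
    subs, indels = _alignment_ops(aln)
    cut = design.cut_sites[0]
    if indels:
        pos, size = indels[0]
        pos = _left_align_indel(pos, size, design.reference_seq)
        net = sum(s for _, s in indels)
        return ReadClassification("indel", indel=(net, pos - cut))
    if not subs:
        return ReadClassification("WT")
    marker = {(p, alt) for p, _, alt in design.marker_edits}
    observed = {(p, alt) for p, _, alt in subs}
    if not marker <= observed:
        return ReadClassification("rejected_other")
    rest = [s for s in subs if (s[0], s[2]) not in marker]
    s0, e0 = design.target_region
    if all(s0 <= p < e0 for p, _, _ in rest):
        key = variant_key_from_amplicon_edits(design, rest)
        return ReadClassification("HDR_variant", variant=key)
    return ReadClassification("rejected_other")


def call_sample(
    reads: Iterable[FastqRead | str],
    design: AmpliconDesign,
    scoring: AlignScoring = AlignScoring(),
    min_score_frac: float = 0.6,
) -> tuple[list[ReadClassification], int]:
    """Align and classify merged reads for one sample.

    Reads scoring below ``min_score_frac`` of the perfect self-alignment
    score are treated as alignment failures and excluded from the sample
    total.  Returns ``(classifications, n_alignment_failures)``.
    """
    ref = design.reference_seq
    perfect = scoring.match * len(ref)
    out: list[ReadClassification] = []
    failures = 0
    for r in reads:
        seq = r.seq if isinstance(r, FastqRead) else r
        if "N" in seq:
            # removed before alignment, mirroring the merged-read N filter
            out.append(ReadClassification("rejected_N"))
            continue
        aln = align_global(seq, ref, scoring)
        if aln.score < min_score_frac * perfect:
            failures += 1
            continue
        out.append(classify_read(aln, design))
    return out, failures


def count_variants(
    classifications: dict[str, Sequence[ReadClassification]],
) -> CountTable:
    """Aggregate per-sample classifications into a :class:`CountTable`.

    ``classifications`` maps sample name to the output of
    :func:`call_sample`.  Totals count every aligned read (all categories
    except pre-alignment N removals and alignment failures).
    """
    per_sample: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    for sample, cls in classifications.items():
        counts: dict[str, int] = {}
        total = 0
        for c in cls:
            if c.category == "rejected_N":
                continue
            total += 1
            if c.category == "HDR_variant":
                row = c.variant.hgvs_c
            elif c.category == "indel":
                row = indel_row(*c.indel)
            elif c.category == "WT":
                row = WT_ROW
            else:
                continue
            counts[row] = counts.get(row, 0) + 1
        per_sample[sample] = counts
        totals[sample] = total
    counts_df = pd.DataFrame(per_sample).fillna(0).astype(int)
    counts_df = counts_df.reindex(sorted(counts_df.index))
    return CountTable(counts_df, pd.Series(totals))


# ---------------------------------------------------------------------------
# summaries


@dataclass
class IndelSpectrum:
    """Indel frequencies by size and by position offset from the cut.

    ``by_size`` / ``by_position``: frequency (count / total aligned reads)
    matrices with samples as columns.  ``z_by_size``: per-size-bin z-score
    across samples (rows with zero spread are set to 0).
    """

    by_size: pd.DataFrame
    by_position: pd.DataFrame
    z_by_size: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        mean = self.by_size.mean(axis=1)
        sd = self.by_size.std(axis=1, ddof=0)
        z = self.by_size.sub(mean, axis=0).div(sd.where(sd > 0), axis=0)
        self.z_by_size = z.fillna(0.0)


def compute_indel_spectrum(table: CountTable) -> IndelSpectrum:
    rows = table.indel_rows()
    if not rows:
        raise ValueError("count table has no indel pseudo-keys")
    if (table.totals <= 0).any():
        raise ValueError("zero total reads: indel frequency undefined")
    freq = table.counts.loc[rows].div(table.totals, axis=1)
    sizes = [parse_indel_row(r)[0] for r in rows]
    offsets = [parse_indel_row(r)[1] for r in rows]
    by_size = freq.groupby(pd.Index(sizes, name="size")).sum().sort_index()
    by_pos = freq.groupby(pd.Index(offsets, name="offset")).sum().sort_index()
    return IndelSpectrum(by_size, by_pos)


def compute_editing_summary(table: CountTable) -> pd.DataFrame:
    """Percent HDR and percent indel reads per sample.

    HDR reads are all marker-gated rows (library variants plus the
    marker-only ``c.=`` allele).
    """
    if (table.totals <= 0).any():
        raise ValueError("zero total reads")
    hdr = table.counts.loc[table.variant_rows()].sum(axis=0)
    ind = table.counts.loc[table.indel_rows()].sum(axis=0) if table.indel_rows() else 0
    return pd.DataFrame(
        {
            "pct_hdr": 100.0 * hdr / table.totals,
            "pct_indel": 100.0 * ind / table.totals,
        }
    )
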