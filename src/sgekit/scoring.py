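"""Frequencies, function scores, filters and the weighted global ratio.

A variant's function score (FS) in one arm is the log2 ratio of its
pseudocounted read frequency at day 14 to its day-3 frequency; frequencies
are normalized to the per-sample total of aligned reads, never to the sum
over variants.  Two filtering paths are provided: the codon-library path
(day-3 frequency must exceed 1e-5 in every replicate) and the
SNV-saturation path (additionally a day-3 count floor of 10 and a
replicate/condition discordance rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sgekit.tables import CONDITIONS, CountTable, REPLICATES, sample_name

#: keep requires day-3 frequency strictly above this in every replicate
DAY3_FREQ_THRESHOLD = 1e-5
#: SNV-path floor on raw day-3 counts
DAY3_COUNT_FLOOR = 10
#: fold difference between replicate post/pre ratios that marks discordance
REPLICATE_FOLD_LIMIT = 2.0

#: weighted global post/pre ratio weights (normalized by their 0.9 sum)
GLOBAL_RATIO_WEIGHTS = {"DMSO": 0.4, "cisplatin": 0.25, "olaparib": 0.25}


@dataclass
class FrequencyTable:
    """Per-variant per-sample frequencies, (count + 1) / sample total."""

    freq: pd.DataFrame
    counts: pd.DataFrame
    totals: pd.Series


@dataclass
class FilterReport:
    """Which variants each filter removed, and what survived."""

    flags: pd.DataFrame      # boolean columns per filter, indexed by variant
    removed: pd.Index
    surviving: pd.Index

    def summary(self) -> pd.Series:
        s = self.flags.sum(axis=0)
        s["removed"] = len(self.removed)
        s["surviving"] = len(self.surviving)
        return s.astype(int)


def normalize_frequencies(table: CountTable) -> FrequencyTable:
    """Pseudocounted frequencies over the per-sample aligned-read totals."""
    if (table.totals <= 0).any():
        raise ValueError("per-sample totals must be positive")
    variants = table.variant_rows()
    counts = table.counts.loc[variants]
    freq = (counts + 1).div(table.totals, axis=1)
    return FrequencyTable(freq, counts, table.totals)


def _day3(freq: FrequencyTable, rep: int) -> pd.Series:
    return freq.freq[sample_name(3, "pre", rep)]


def compute_fs(freq: FrequencyTable) -> pd.DataFrame:
    """Function scores per condition, per replicate and replicate-averaged.

    Columns: ``fs_<cond>_r<k>``, ``fs_<cond>`` (mean over replicates) and
    ``ratio_<cond>`` (the linear-scale mean post/pre ratio used by the
    SNV-saturation path).
    """
    out = pd.DataFrame(index=freq.freq.index)
    for cond in CONDITIONS:
        per_rep = []
        ratios = []
        for rep in REPLICATES:
            ratio = freq.freq[sample_name(14, cond, rep)] / _day3(freq, rep)
            ratios.append(ratio)
            fs = np.log2(ratio)
            out[f"fs_{cond}_r{rep}"] = fs
            out[f"ratio_{cond}_r{rep}"] = ratio
            per_rep.append(fs)
        out[f"fs_{cond}"] = sum(per_rep) / len(per_rep)
        out[f"ratio_{cond}"] = sum(ratios) / len(ratios)
    return out


def apply_codon_filters(freq: FrequencyTable) -> FilterReport:
    """Codon-library filter: day-3 frequency must exceed 1e-5 in *every*
    replicate; a single low replicate removes the variant.  The boundary
    value 1e-5 itself is removed (keeping requires strictly more than one
    read in 1e5)."""
    flags = pd.DataFrame(index=freq.freq.index)
    low = pd.Series(False, index=freq.freq.index)
    for rep in REPLICATES:
        low |= _day3(freq, rep) <= DAY3_FREQ_THRESHOLD
    flags["low_freq"] = low
    removed = flags.index[flags.any(axis=1)]
    return FilterReport(flags, removed, flags.index.difference(removed))


def _prelim_calls(fs: pd.DataFrame, controls: pd.Series) -> pd.DataFrame:
    """Per-replicate, per-condition preliminary class call.

    The call compares each replicate's log2 ratio with the midpoint of the
    synonymous-control and nonsense-control medians for that replicate and
    condition; above the midpoint is "functional".  ``controls`` maps
    variants to {"functional", "non_functional"} (others absent/NaN).
    """
    calls = pd.DataFrame(index=fs.index)
    syn = controls[controls == "functional"].index.intersection(fs.index)
    non = controls[controls == "non_functional"].index.intersection(fs.index)
    if len(syn) == 0 or len(non) == 0:
        raise ValueError("preliminary calls need both control classes")
    for cond in CONDITIONS:
        for rep in REPLICATES:
            col = f"fs_{cond}_r{rep}"
            mid = (fs.loc[syn, col].median() + fs.loc[non, col].median()) / 2.0
            calls[f"call_{cond}_r{rep}"] = np.where(fs[col] > mid,
                                                    "functional", "non_functional")
    return calls


def apply_exon13_filters(
    freq: FrequencyTable,
    fs: pd.DataFrame,
    controls: pd.Series,
    fold_limit: float = REPLICATE_FOLD_LIMIT,
    fold_change_mode: bool = True,
) -> FilterReport:
    """SNV-saturation filters.

    Removes variants with (i) a day-3 raw count below 10 or day-3
    frequency at/below 1e-5 in any replicate; (ii) DMSO replicate post/pre
    ratios differing by more than ``fold_limit`` *and* divergent
    per-replicate class calls; (iii) the same two-part discordance in two
    or more conditions.  ``fold_change_mode=True`` reads "difference of
    more than 2" as a fold change (max/min of the replicate ratios);
    ``False`` uses the arithmetic difference.
    """
    flags = pd.DataFrame(index=freq.freq.index)
    low_count = pd.Series(False, index=freq.freq.index)
    low_freq = pd.Series(False, index=freq.freq.index)
    for rep in REPLICATES:
        s = sample_name(3, "pre", rep)
        low_count |= freq.counts[s] < DAY3_COUNT_FLOOR
        low_freq |= freq.freq[s] <= DAY3_FREQ_THRESHOLD
    flags["low_day3_count"] = low_count
    flags["low_freq"] = low_freq

    calls = _prelim_calls(fs, controls)
    discord = {}
    for cond in CONDITIONS:
        r1 = fs[f"ratio_{cond}_r1"]
        r2 = fs[f"ratio_{cond}_r2"]
        if fold_change_mode:
            big = np.maximum(r1, r2) / np.minimum(r1, r2) > fold_limit
        else:
            big = (r1 - r2).abs() > fold_limit
        diverge = calls[f"call_{cond}_r1"] != calls[f"call_{cond}_r2"]
        discord[cond] = big & diverge
    flags["replicate_discordant"] = (
        discord["DMSO"] | (sum(d.astype(int) for d in discord.values()) >= 2)
    )
    removed = flags.index[flags.any(axis=1)]
    return FilterReport(flags, removed, flags.index.difference(removed))


def compute_global_ratio(
    fs: pd.DataFrame,
    weights: dict[str, float] | None = None,
) -> pd.Series:
    """Weighted mean of the per-condition mean post/pre ratios.

    The stated weights (0.4 DMSO, 0.25 each drug arm) sum to 0.9, so the
    mean is normalized by the weight sum.  The log2 of this quantity is
    the raw score of the SNV-saturation path.
    """
    w = weights or GLOBAL_RATIO_WEIGHTS
    missing = [c for c in w if f"ratio_{c}" not in fs.columns]
    if missing:
        raise ValueError(f"missing condition ratios: {missing}")
    total = sum(w.values())
    acc = sum(w[c] * fs[f"ratio_{c}"] for c in w)
    return acc / total
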