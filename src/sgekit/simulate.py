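"""Ground-truthed synthetic SGE experiments.

The generator realizes the statistical structure the analysis assumes: a
small HDR fraction of day-3 alleles carrying the marker plus one library
variant each, an NHEJ indel fraction centered on the cut site, and day-14
abundances driven by per-class log2 fold changes — functional variants
ride along with wild type, non-functional variants drop out in every arm,
and hypomorphs drop out only under cisplatin/olaparib selection.  Counts
are multinomial at fixed per-sample depth, so totals are exact; optional
FASTQ output exercises the merger/aligner with the true allele recorded in
every read name.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from sgekit.caller import FastqRead, _revcomp
from sgekit.design import AmpliconDesign, VariantKey, annotate_consequence
from sgekit.tables import WT_ROW, CountTable, all_samples, indel_row


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the assay being emulated: 2e6 reads per sample
    (MiSeq amplicon coverage of 1-3 million), ~1% HDR (observed range
    0.3-2.3%), day-3 to day-14 dropout of about -3 log2 units for
    non-functional variants, and hypomorphs that are near-neutral in DMSO
    but depleted roughly -2 log2 units under drug selection.
    """

    seed: int = 0
    depth_per_sample: int = 2_000_000
    hdr_rate: float = 0.01
    indel_rate: float = 0.2
    # per-class log2 fold-change distributions (day 14 vs day 3)
    functional_mean: float = 0.0
    functional_sd: float = 0.3
    nonfunctional_mean: float = -3.0
    nonfunctional_sd: float = 0.5
    hypomorph_dmso_mean: float = 0.0
    hypomorph_dmso_sd: float = 0.3
    hypomorph_drug_mean: float = -2.0
    hypomorph_drug_sd: float = 0.5
    # class mix among variants whose class is not forced by their consequence
    functional_fraction: float = 0.50
    nonfunctional_fraction: float = 0.45
    hypomorph_fraction: float = 0.05
    replicate_noise_sd: float = 0.1
    position_bias_amplitude: float = 0.0
    dirichlet_concentration: float = 50.0
    # read-level parameters
    reads_per_sample: int = 5000
    read_length: int = 150
    seq_error_rate: float = 0.001
    n_read_fraction: float = 0.0
    indel_max_size: int = 10

    def __post_init__(self) -> None:
        for name in ("hdr_rate", "indel_rate", "seq_error_rate", "n_read_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.hdr_rate + self.indel_rate > 1.0:
            raise ValueError("hdr_rate + indel_rate exceeds 1")
        fracs = (self.functional_fraction, self.nonfunctional_fraction,
                 self.hypomorph_fraction)
        if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("class fractions must be non-negative and sum to 1")
        if self.depth_per_sample <= 0 or self.reads_per_sample <= 0:
            raise ValueError("depth must be positive")
        for name in ("functional_sd", "nonfunctional_sd", "hypomorph_dmso_sd",
                     "hypomorph_drug_sd", "replicate_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """True classes, per-arm log2 fold changes and day-3 abundances.

    ``variants`` is indexed by HGVS c. key with columns ``consequence``,
    ``true_class``, ``lfc_<arm>``, ``day3_abundance`` (shares of the HDR
    pool, summing to 1) and ``position``.  ``indels`` describes the NHEJ
    allele pool analogously.
    """

    variants: pd.DataFrame
    indels: pd.DataFrame
    keys: dict[str, VariantKey]
    config: SimulationConfig


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


_ARMS = ("DMSO", "cisplatin", "olaparib")


def simulate_ground_truth(
    library: Sequence[VariantKey],
    config: SimulationConfig,
    design: AmpliconDesign | None = None,
) -> GroundTruth:
    """Assign true classes and effects to a variant library.

    Classes forced by consequence: synonymous (and the marker-only allele)
    are functional, nonsense are non-functional, splice-region variants are
    non-functional, deep-intronic variants are functional.  Missense
    variants are assigned by the configured class mix.
    """
    if not library:
        raise ValueError("empty library")
    rng = _rng(config, 0)
    rows = []
    keys: dict[str, VariantKey] = {}
    for key in library:
        if key.hgvs_c in keys:
            continue
        keys[key.hgvs_c] = key
        if design is not None:
            cons = annotate_consequence(design, key).kind
        else:
            cons = _infer_kind(key)
        rows.append((key.hgvs_c, cons))
    df = pd.DataFrame(rows, columns=["variant", "consequence"]).set_index("variant")

    forced = {
        "synonymous": "functional",
        "nonsense": "non_functional",
        "splice_region": "non_functional",
        "intronic": "functional",
    }
    classes = []
    mix = ("functional", "non_functional", "hypomorph")
    probs = (config.functional_fraction, config.nonfunctional_fraction,
             config.hypomorph_fraction)
    for cons in df["consequence"]:
        if cons in forced:
            classes.append(forced[cons])
        else:
            classes.append(rng.choice(mix, p=probs))
    df["true_class"] = classes

    n = len(df)
    draws = {
        "functional": rng.normal(config.functional_mean, config.functional_sd,
                                 (n, 3)),
        "non_functional": rng.normal(config.nonfunctional_mean,
                                     config.nonfunctional_sd, (n, 3)),
        "hypomorph": np.column_stack([
            rng.normal(config.hypomorph_dmso_mean, config.hypomorph_dmso_sd, n),
            rng.normal(config.hypomorph_drug_mean, config.hypomorph_drug_sd, n),
            rng.normal(config.hypomorph_drug_mean, config.hypomorph_drug_sd, n),
        ]),
    }
    for j, arm in enumerate(_ARMS):
        df[f"lfc_{arm}"] = [draws[c][i, j] for i, c in enumerate(df["true_class"])]

    conc = config.dirichlet_concentration
    df["day3_abundance"] = rng.dirichlet(np.full(n, conc))
    positions = []
    for v in df.index:
        key = keys[v]
        if key.edits:
            cp = key.edits[0][0]
            positions.append(cp.base + cp.offset)
        else:
            positions.append(np.nan)
    df["position"] = positions
    df["position"] = df["position"].fillna(df["position"].mean())

    indels = _simulate_indel_pool(config, rng, design)
    return GroundTruth(df, indels, keys, config)


def _infer_kind(key: VariantKey) -> str:
    """Coarse consequence when no design is supplied (from hgvs_p/edits)."""
    if key.is_marker_only:
        return "synonymous"
    if any(not cp.is_exonic for cp, _, _ in key.edits):
        offs = [abs(cp.offset) for cp, _, _ in key.edits if not cp.is_exonic]
        return "splice_region" if min(offs) <= 2 else "intronic"
    if key.hgvs_p.endswith("*"):
        return "nonsense"
    if key.hgvs_p.endswith("="):
        return "synonymous"
    return "missense"


def _simulate_indel_pool(
    config: SimulationConfig,
    rng: np.random.Generator,
    design: AmpliconDesign | None,
) -> pd.DataFrame:
    """NHEJ allele pool: sizes geometric-tailed, positions near the cut."""
    n_alleles = 12
    sizes = []
    for _ in range(n_alleles):
        mag = min(int(rng.geometric(0.45)), config.indel_max_size)
        sign = -1 if rng.random() < 0.75 else 1  # deletions dominate
        sizes.append(sign * mag)
    offsets = np.clip(np.round(rng.normal(0, 2, n_alleles)), -8, 8).astype(int)
    inserts = [
        "".join(rng.choice(list("ACGT"), max(s, 0))) if s > 0 else ""
        for s in sizes
    ]
    rows = {}
    for size, off, ins in zip(sizes, offsets, inserts):
        size, off = int(size), int(off)
        if design is not None:
            # canonicalize through the caller: align the pure allele and
            # record the (size, offset) the pipeline itself will report,
            # so noiseless reads round-trip exactly
            from sgekit.caller import align_global, classify_read

            cut = design.cut_sites[0]
            ref = design.reference_seq
            pos = int(np.clip(cut + off, 1, len(ref) - abs(size) - 1))
            if size < 0:
                allele = ref[:pos] + ref[pos - size:]
            else:
                allele = ref[:pos] + ins + ref[pos:]
            cls = classify_read(align_global(allele, ref), design)
            if cls.category != "indel":
                continue
            construct_size, construct_offset = size, pos - cut
            size, off = cls.indel
        else:
            construct_size, construct_offset = size, off
        rid = indel_row(size, off)
        if rid in rows:
            continue
        out_of_frame = construct_size % 3 != 0
        lfc = config.nonfunctional_mean if out_of_frame else 0.0
        rows[rid] = dict(size=size, offset=off, insert_seq=ins,
                         construct_size=construct_size,
                         construct_offset=construct_offset,
                         out_of_frame=out_of_frame,
                         **{f"lfc_{a}": lfc for a in _ARMS})
    df = pd.DataFrame.from_dict(rows, orient="index")
    df["abundance"] = rng.dirichlet(np.full(len(df), 10.0))
    return df


# ---------------------------------------------------------------------------


def _allele_frame(truth: GroundTruth) -> pd.DataFrame:
    """Stack WT, variants and indels with day-3 frequency and per-arm lfc."""
    cfg = truth.config
    v = truth.variants
    rows = [
        {"allele": WT_ROW, "freq3": 1.0 - cfg.hdr_rate - cfg.indel_rate,
         **{f"lfc_{a}": 0.0 for a in _ARMS}, "position": np.nan}
    ]
    for var, r in v.iterrows():
        rows.append({
            "allele": var,
            "freq3": cfg.hdr_rate * r["day3_abundance"],
            **{f"lfc_{a}": r[f"lfc_{a}"] for a in _ARMS},
            "position": r["position"],
        })
    for rid, r in truth.indels.iterrows():
        rows.append({
            "allele": rid,
            "freq3": cfg.indel_rate * r["abundance"],
            **{f"lfc_{a}": r[f"lfc_{a}"] for a in _ARMS},
            "position": np.nan,
        })
    return pd.DataFrame(rows).set_index("allele")


def _bias_term(positions: pd.Series, amplitude: float) -> np.ndarray:
    """Smooth positional trend on the log2 ratio (sinusoid over the library span)."""
    if amplitude == 0.0:
        return np.zeros(len(positions))
    pos = positions.to_numpy(float)
    finite = np.isfinite(pos)
    lo, hi = np.nanmin(pos), np.nanmax(pos)
    span = max(hi - lo, 1.0)
    out = np.zeros(len(pos))
    out[finite] = amplitude * np.sin(2.0 * np.pi * (pos[finite] - lo) / span)
    return out


def _sample_freqs(
    truth: GroundTruth, rng: np.random.Generator
) -> pd.DataFrame:
    """Expected allele frequencies for each of the 8 samples."""
    cfg = truth.config
    alleles = _allele_frame(truth)
    bias = _bias_term(alleles["position"], cfg.position_bias_amplitude)
    is_variant = alleles.index.str.startswith("c.")
    freqs = {}
    for s in all_samples():
        if s.day == 3:
            freqs[s.name] = alleles["freq3"].to_numpy()
            continue
        noise = rng.normal(0.0, cfg.replicate_noise_sd, len(alleles))
        lfc = alleles[f"lfc_{s.condition}"].to_numpy() + noise
        lfc = lfc + np.where(is_variant, bias, 0.0)
        w = alleles["freq3"].to_numpy() * np.exp2(lfc)
        freqs[s.name] = w / w.sum()
    return pd.DataFrame(freqs, index=alleles.index)


def simulate_counts(truth: GroundTruth, config: SimulationConfig | None = None) -> CountTable:
    """Multinomial day-3/day-14 read counts at fixed per-sample depth."""
    cfg = config or truth.config
    if cfg is not truth.config:
        truth = replace_config(truth, cfg)
    rng = _rng(cfg, 1)
    freqs = _sample_freqs(truth, rng)
    counts = {
        name: rng.multinomial(cfg.depth_per_sample, col.to_numpy())
        for name, col in freqs.items()
    }
    df = pd.DataFrame(counts, index=freqs.index)
    totals = pd.Series(cfg.depth_per_sample, index=df.columns)
    return CountTable(df, totals)


def replace_config(truth: GroundTruth, config: SimulationConfig) -> GroundTruth:
    return GroundTruth(truth.variants, truth.indels, truth.keys, config)


# ---------------------------------------------------------------------------
# read-level simulation


def _allele_sequence(allele: str, truth: GroundTruth, design: AmpliconDesign) -> str:
    if allele == WT_ROW:
        return design.reference_seq
    if allele.startswith("c."):
        key = truth.keys[allele]
        return design.apply_edits(key.edits, with_marker=True)
    r = truth.indels.loc[allele]
    cut = design.cut_sites[0]
    pos = cut + int(r["construct_offset"])
    ref = design.reference_seq
    if r["construct_size"] < 0:
        return ref[:pos] + ref[pos - int(r["construct_size"]):]
    return ref[:pos] + r["insert_seq"] + ref[pos:]


def simulate_reads(
    truth: GroundTruth,
    design: AmpliconDesign,
    config: SimulationConfig | None = None,
    samples: Iterable[str] | None = None,
) -> tuple[dict[str, tuple[list[FastqRead], list[FastqRead]]], CountTable]:
    """Emit overlapping paired reads per sample, plus the true allele counts.

    Each pair covers the allele from both ends at ``read_length``, so the
    mates overlap in the middle and exercise the merger.  Per-base errors
    are applied at ``seq_error_rate``; a fraction ``n_read_fraction`` of
    pairs receives an ``N`` base.  The true allele id is embedded in every
    read name (``sample|allele|serial``) for test assertions.

    Returns ``(reads, true_counts)`` where ``true_counts`` holds the drawn
    per-sample allele counts in caller row conventions.
    """
    cfg = config or truth.config
    if cfg is not truth.config:
        truth = replace_config(truth, cfg)
    rng = _rng(cfg, 2)
    freqs = _sample_freqs(truth, rng)
    wanted = list(samples) if samples is not None else list(freqs.columns)
    seqs = {a: _allele_sequence(a, truth, design) for a in freqs.index}
    bases = np.array(list("ACGT"))
    reads: dict[str, tuple[list[FastqRead], list[FastqRead]]] = {}
    count_cols = {}
    for name in wanted:
        alleles = freqs.index.to_numpy()
        n_per = rng.multinomial(cfg.reads_per_sample, freqs[name].to_numpy())
        count_cols[name] = pd.Series(n_per, index=freqs.index)
        r1s: list[FastqRead] = []
        r2s: list[FastqRead] = []
        serial = 0
        for allele, n_reads in zip(alleles, n_per):
            seq = seqs[allele]
            L = min(cfg.read_length, len(seq))
            for _ in range(n_reads):
                fwd = list(seq[:L])
                rev = list(_revcomp(seq)[:L])
                for arr in (fwd, rev):
                    if cfg.seq_error_rate > 0:
                        hits = np.nonzero(rng.random(len(arr)) < cfg.seq_error_rate)[0]
                        for h in hits:
                            arr[h] = rng.choice(bases[bases != arr[h]])
                if cfg.n_read_fraction > 0 and rng.random() < cfg.n_read_fraction:
                    fwd[rng.integers(0, len(fwd))] = "N"
                rid = f"{name}|{allele}|{serial}"
                serial += 1
                qual = tuple([35] * L)
                r1s.append(FastqRead(rid, "".join(fwd), qual))
                r2s.append(FastqRead(rid, "".join(rev), qual))
        order = rng.permutation(len(r1s))
        reads[name] = ([r1s[i] for i in order], [r2s[i] for i in order])
    counts_df = pd.DataFrame(count_cols)
    totals = counts_df.sum(axis=0)
    return reads, CountTable(counts_df, totals)
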