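"""Synthetic demonstration designs.

Real SGE amplicon sequences are proprietary to each assay; these builders
construct fully synthetic stand-ins with the same structure — an exonic
core flanked by intron, a Cas9 cut site inside the saturated region, and a
synonymous (or intronic) PAM-marker edit — so examples, tests and the
acceptance script can run self-contained.  Sequences are generated from a
fixed seed and are stable across runs.
"""

from __future__ import annotations

import numpy as np

from sgekit.design import AmpliconDesign

_BASES = list("ACGT")


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, n))


def codon_design(seed: int = 7, n_codons: int = 3) -> AmpliconDesign:
    """Codon-saturation amplicon: ``n_codons`` target codons in one exon.

    Mirrors the 11-codon arm of the assay at adjustable scale: the exon
    covers c.150 onward, the saturated codons start at residue 57
    (c.169-171, wild type TAC, so ``c.171C>A`` is the p.Tyr57* nonsense
    change), the marker is a synonymous third-base edit in codon 56 and
    the cut falls right after codon 57.
    """
    if not 1 <= n_codons <= 11:
        raise ValueError("n_codons must be between 1 and 11")
    rng = np.random.default_rng(seed)
    fixed = {56: "CTG", 57: "TAC", 58: "GAA", 59: "CCT"}
    last_c = max(200, 3 * (57 + n_codons) + 9)
    exon = []
    for c in range(150, last_c + 1):
        aa = (c - 1) // 3 + 1
        k = (c - 1) % 3
        if aa in fixed:
            exon.append(fixed[aa][k])
        else:
            exon.append(rng.choice(_BASES))
    # keep the wild-type frame stop-free outside the fixed codons
    for aa0 in range((150 - 1) // 3 + 2, (last_c - 1) // 3 + 1):
        i = (3 * aa0 - 2) - 150
        if "".join(exon[i:i + 3]) in ("TAA", "TAG", "TGA"):
            exon[i] = "C"
    ref = _random_bases(rng, 30) + "".join(exon) + _random_bases(rng, 30)
    marker_pos = 30 + (168 - 150)  # third base of codon 56 (CTG -> CTC, Leu)
    target_start = 30 + (169 - 150)
    return AmpliconDesign(
        amplicon_id="toy_codon",
        reference_seq=ref,
        exon_intervals=[(30, 30 + (last_c - 150 + 1))],
        cdna_offset=149,
        cut_sites=[30 + (171 - 150) + 1],
        marker_edits=[(marker_pos, ref[marker_pos], "C")],
        target_region=(target_start, target_start + 3 * n_codons),
    )


def snv_design(seed: int = 11) -> AmpliconDesign:
    """SNV-saturation amplicon patterned on an exon-13-style experiment.

    A 70-nt exon at c.6938-c.7007 with 40-nt intron flanks; the target
    region runs from 12 nt into the upstream intron to 7 nt past the exon
    (89 positions, 267 possible SNVs).  The exon starts mid-codon, as the
    real exon does, so the first two exonic bases cannot be confirmed
    synonymous/nonsense from the amplicon alone.  The marker edit sits in
    the downstream intron, outside the scored positions.
    """
    rng = np.random.default_rng(seed)
    codon_slots = [((c - 1) // 3 + 1, (c - 1) % 3) for c in range(6938, 7008)]
    aa_numbers = sorted({aa for aa, _ in codon_slots})
    codons = {aa: "".join(rng.choice(_BASES, 3)) for aa in aa_numbers}
    for aa, codon in codons.items():  # keep the wild-type frame stop-free
        if codon in ("TAA", "TAG", "TGA"):
            codons[aa] = "C" + codon[1:]
    exon_seq = "".join(codons[aa][k] for aa, k in codon_slots)
    ref = _random_bases(rng, 40) + exon_seq + _random_bases(rng, 40)
    exon_start = 40
    exon_end = 40 + len(exon_seq)
    marker_pos = exon_end + 12  # intronic, outside the target region
    alt = "A" if ref[marker_pos] != "A" else "G"
    return AmpliconDesign(
        amplicon_id="toy_snv",
        reference_seq=ref,
        exon_intervals=[(exon_start, exon_end)],
        cdna_offset=6937,  # first exonic base is c.6938
        cut_sites=[exon_start + 35],
        marker_edits=[(marker_pos, ref[marker_pos], alt)],
        target_region=(exon_start - 12, exon_end + 7),
    )
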