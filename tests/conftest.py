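"""Shared fixtures: synthetic designs, libraries and simulated tables."""

from __future__ import annotations

import numpy as np
import pytest

from sgekit.design import AmpliconDesign, enumerate_codon_library, enumerate_snv_library
from sgekit.presets import codon_design, snv_design
from sgekit.simulate import SimulationConfig, simulate_counts, simulate_ground_truth

FS_COLS = ["fs_DMSO", "fs_cisplatin", "fs_olaparib"]


def build_design(fixed_codons: dict[int, str], n_target_codons: int = 3,
                 seed: int = 7) -> AmpliconDesign:
    """Custom single-exon design (exon c.150+, marker CTG->CTC at codon 56).

    ``fixed_codons`` pins specific codons (residue number -> triplet);
    everything else is seeded-random.  Target codons start at residue 57.
    """
    rng = np.random.default_rng(seed)
    fixed = {56: "CTG", **fixed_codons}
    last_c = max(200, 3 * (57 + n_target_codons) + 9)
    exon = []
    for c in range(150, last_c + 1):
        aa = (c - 1) // 3 + 1
        k = (c - 1) % 3
        exon.append(fixed[aa][k] if aa in fixed else rng.choice(list("ACGT")))
    ref = ("".join(rng.choice(list("ACGT"), 30)) + "".join(exon)
           + "".join(rng.choice(list("ACGT"), 30)))
    marker_pos = 30 + (168 - 150)
    target_start = 30 + (169 - 150)
    return AmpliconDesign(
        amplicon_id="custom",
        reference_seq=ref,
        exon_intervals=[(30, 30 + (last_c - 150 + 1))],
        cdna_offset=149,
        cut_sites=[30 + (171 - 150) + 1],
        marker_edits=[(marker_pos, ref[marker_pos], "C")],
        target_region=(target_start, target_start + 3 * n_target_codons),
    )


@pytest.fixture(scope="session")
def toy_design():
    return codon_design()


@pytest.fixture(scope="session")
def toy_library(toy_design):
    return [k for aa in (57, 58, 59)
            for k in enumerate_codon_library(toy_design, aa)]


@pytest.fixture(scope="session")
def exon13_design():
    return snv_design()


@pytest.fixture(scope="session")
def exon13_library(exon13_design):
    return enumerate_snv_library(exon13_design, "6938-12", "7007+7")


@pytest.fixture(scope="session")
def study_design():
    """Six saturated codons: control counts comparable to the real assay."""
    return codon_design(n_codons=6)


@pytest.fixture(scope="session")
def study_library(study_design):
    return [k for aa in range(57, 63)
            for k in enumerate_codon_library(study_design, aa)]


@pytest.fixture(scope="session")
def study_truth_counts(study_design, study_library):
    cfg = SimulationConfig(seed=1)
    truth = simulate_ground_truth(study_library, cfg, study_design)
    return truth, simulate_counts(truth)
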