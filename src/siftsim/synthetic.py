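"""Seeded generator of synthetic interaction-fingerprint datasets.

The generator emulates the statistical structure of a docking-based
virtual-screening set without any 3D input:

* a reference fingerprint (the known active's interaction pattern), drawn
  bitwise Bernoulli(``p_ref``) over a residues x 9-interaction-types grid;
* actives that share most of the reference pattern — each bit of the
  reference flipped independently with probability ``flip_active``;
* decoys that overlap the reference much less — flips at ``flip_decoy``
  (> ``flip_active``);
* a fraction of residues that never interact (their whole 9-bit block is
  zero across the dataset), plus additional single interaction columns
  that can never be established (e.g. an aromatic bit on a residue with no
  aromatic ring), so the RES and INTS filtering rules have work to do.

The reference-anchored bit-flip model encodes graded overlap with a single
parameter per class: actives resemble the reference's binding mode, decoys
are chemically plausible but bind differently, which is exactly the
contrast the consensus reference and the ROC analysis exploit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fingerprints import (
    INTERACTION_TYPES,
    BitLayout,
    FingerprintDataset,
    InteractionFingerprint,
)

#: 3-letter residue codes used to synthesize residue identifiers.
_AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic fingerprint generator.

    Defaults describe a desk-scale virtual-screening set with the sparsity
    pattern of real SIFt data, where the large majority of enumerated bits
    are consistently zero: 64 residues of which three quarters never
    interact, a further 30% of the remaining columns impossible by
    definition, sparse reference interactions, nearly reference-like
    actives and heavily corrupted decoys at a 1:3 active:decoy ratio.
    """

    n_residues: int = 64
    n_actives: int = 40
    n_decoys: int = 120
    p_ref: float = 0.25
    flip_active: float = 0.05
    flip_decoy: float = 0.4
    frac_silent_residues: float = 0.75
    frac_impossible_bits: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_ref", "flip_active", "flip_decoy",
                     "frac_silent_residues", "frac_impossible_bits"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.flip_decoy < self.flip_active:
            raise ValueError("flip_decoy must be >= flip_active")
        for name in ("n_residues", "n_actives", "n_decoys"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def generate_dataset(
    config: SynthConfig, name: str | None = None
) -> tuple[FingerprintDataset, InteractionFingerprint]:
    """Generate a synthetic dataset and its reference fingerprint.

    Deterministic given ``config.seed``. The layout is
    ``n_residues`` x 9 canonical interaction types; silent residues and
    impossible bits are zeroed in the reference and every ligand.
    """
    rng = np.random.default_rng(config.seed)
    n_types = len(INTERACTION_TYPES)
    layout = BitLayout(_residue_names(rng, config.n_residues))
    n_bits = len(layout)

    n_silent = int(round(config.frac_silent_residues * config.n_residues))
    if n_silent >= config.n_residues:
        raise ValueError("config silences every residue; nothing left to compare")
    silent = rng.choice(config.n_residues, size=n_silent, replace=False)
    possible = np.ones(n_bits, dtype=bool)
    for r in silent:
        possible[r * n_types:(r + 1) * n_types] = False

    # impossible bits: single columns inside interacting residues, never the
    # "Any contact" column (a contact is possible by definition)
    pool = np.flatnonzero(possible)
    pool = pool[pool % n_types != 0]
    n_impossible = int(round(config.frac_impossible_bits * pool.size))
    impossible = rng.choice(pool, size=n_impossible, replace=False) if n_impossible else []
    possible[impossible] = False
    if not possible.any():
        raise ValueError("config leaves no establishable interaction column")

    reference = (rng.random(n_bits) < config.p_ref).astype(np.uint8)
    reference[~possible] = 0

    fps = []
    for label, count, flip in (
        ("ACT", config.n_actives, config.flip_active),
        ("DEC", config.n_decoys, config.flip_decoy),
    ):
        flips = rng.random((count, n_bits)) < flip
        bits = np.where(flips, 1 - reference, reference).astype(np.uint8)
        bits[:, ~possible] = 0
        width = len(str(count))
        for i in range(count):
            fps.append(
                InteractionFingerprint(
                    f"{label}{i + 1:0{width}d}", bits[i], active=label == "ACT"
                )
            )
    dataset = FingerprintDataset(name or f"synth-{config.seed}", layout, tuple(fps))
    ref_fp = InteractionFingerprint("REF", reference, active=True)
    return dataset, ref_fp


def _residue_names(rng: np.random.Generator, n: int) -> tuple[str, ...]:
    codes = rng.choice(len(_AMINO_ACIDS), size=n)
    positions = np.sort(rng.choice(np.arange(10, 10 + 8 * n), size=n, replace=False))
    return tuple(f"{_AMINO_ACIDS[c]}{p}" for c, p in zip(codes, positions))
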