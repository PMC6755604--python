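"""Interaction-fingerprint data model, CSV I/O, bit selection and filtering.

A structural interaction fingerprint (SIFt) encodes a 3D protein-ligand
complex as a bitstring: for every binding-site residue there is one bit per
interaction type (any contact, backbone, sidechain, polar, hydrophobic,
H-bond acceptor/donor, aromatic, charged), set to 1 when that residue
establishes that interaction with the ligand.

The module provides

* :class:`BitLayout`, :class:`InteractionFingerprint` and
  :class:`FingerprintDataset` containers;
* a plain-CSV reader/writer (``ligand_id,active,RES:INT,...``);
* the bit-selection schemes ``ALL`` (keep all nine interaction types),
  ``WO1`` (drop "Any contact") and ``WO3`` (drop "Any", backbone and
  sidechain contacts);
* the two filtering rules: residue-based filtering (``RES``) removes every
  residue whose whole bit block is zero across the dataset, and
  interaction-based filtering (``INTS``) removes every individual column
  that is never set.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical interaction-type order of the modified SIFt.
INTERACTION_TYPES = ("Any", "BB", "SC", "Pol", "Hyd", "HBA", "HBD", "Aro", "Chg")

#: Interaction types removed by each bit-selection scheme.
BIT_SELECTIONS = {
    "ALL": frozenset(),
    "WO1": frozenset({"Any"}),
    "WO3": frozenset({"Any", "BB", "SC"}),
}

FILTERING_RULES = ("NO", "RES", "INTS")


class FormatError(ValueError):
    """Raised for malformed fingerprint files."""


@dataclass(frozen=True)
class BitLayout:
    """Ordered residue list x ordered interaction-type list.

    Bit index of (residue *i*, interaction *j*) is
    ``i * len(interaction_types) + j``.
    """

    residues: tuple[str, ...]
    interaction_types: tuple[str, ...] = INTERACTION_TYPES

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", tuple(self.residues))
        object.__setattr__(self, "interaction_types", tuple(self.interaction_types))
        unknown = set(self.interaction_types) - set(INTERACTION_TYPES)
        if unknown:
            raise ValueError(f"unknown interaction types: {sorted(unknown)}")
        canon = [t for t in INTERACTION_TYPES if t in self.interaction_types]
        if list(self.interaction_types) != canon:
            raise ValueError(
                "interaction_types must follow the canonical order "
                f"{INTERACTION_TYPES}, got {self.interaction_types}"
            )

    def __len__(self) -> int:
        return len(self.residues) * len(self.interaction_types)

    @property
    def columns(self) -> list[str]:
        """Column names, ``"RESIDUE:INTERACTION"``, in bit order."""
        return [f"{r}:{t}" for r in self.residues for t in self.interaction_types]

    def index_of(self, residue: str, interaction: str) -> int:
        i = self.residues.index(residue)
        j = self.interaction_types.index(interaction)
        return i * len(self.interaction_types) + j


@dataclass(frozen=True)
class InteractionFingerprint:
    """One ligand's binary interaction pattern with an activity label."""

    ligand_id: str
    bits: np.ndarray
    active: bool

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits)
        if arr.ndim != 1:
            raise ValueError("bits must be a 1-D vector")
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError(f"fingerprint {self.ligand_id!r} has non-binary bits")
        object.__setattr__(self, "bits", arr.astype(np.uint8))

    def __len__(self) -> int:
        return self.bits.size


@dataclass(frozen=True)
class FingerprintDataset:
    """An ordered collection of fingerprints sharing one :class:`BitLayout`."""

    name: str
    layout: BitLayout
    fingerprints: tuple[InteractionFingerprint, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "fingerprints", tuple(self.fingerprints))
        n = len(self.layout)
        for fp in self.fingerprints:
            if len(fp) != n:
                raise ValueError(
                    f"fingerprint {fp.ligand_id!r} has {len(fp)} bits, "
                    f"layout defines {n}"
                )

    def __len__(self) -> int:
        return len(self.fingerprints)

    @property
    def bit_matrix(self) -> np.ndarray:
        """(n_ligands, n_bits) uint8 matrix in dataset order."""
        if not self.fingerprints:
            return np.zeros((0, len(self.layout)), dtype=np.uint8)
        return np.vstack([fp.bits for fp in self.fingerprints])

    @property
    def activities(self) -> np.ndarray:
        return np.array([fp.active for fp in self.fingerprints], dtype=bool)

    @property
    def ligand_ids(self) -> list[str]:
        return [fp.ligand_id for fp in self.fingerprints]

# ---------------------------------------------------------------------------
# irregular column subsets (after INTS filtering the residue x type grid is
# ragged, so datasets are also representable with an explicit column list)


@dataclass(frozen=True)
class RaggedLayout:
    """Explicit column list for datasets whose residue x type grid is ragged
    (e.g. after interaction-based filtering)."""

    column_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "column_names", tuple(self.column_names))

    def __len__(self) -> int:
        return len(self.column_names)

    @property
    def columns(self) -> list[str]:
        return list(self.column_names)

    @property
    def residues(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.column_names:
            seen.setdefault(c.split(":", 1)[0])
        return tuple(seen)

    @property
    def interaction_types(self) -> tuple[str, ...]:
        present = {c.split(":", 1)[1] for c in self.column_names}
        return tuple(t for t in INTERACTION_TYPES if t in present)


def _layout_from_columns(columns: list[str]) -> tuple[tuple[str, ...], tuple[str, ...]]:
    residues: dict[str, None] = {}
    types: set[str] = set()
    for col in columns:
        if ":" not in col:
            raise FormatError(f"column {col!r} is not RESIDUE:INTERACTION")
        res, typ = col.split(":", 1)
        if typ not in INTERACTION_TYPES:
            raise FormatError(f"column {col!r} has unknown interaction type {typ!r}")
        residues.setdefault(res)
        types.add(typ)
    ordered_types = tuple(t for t in INTERACTION_TYPES if t in types)
    return tuple(residues), ordered_types


def _is_regular(columns: list[str], residues: tuple[str, ...], types: tuple[str, ...]) -> bool:
    expected = [f"{r}:{t}" for r in residues for t in types]
    return columns == expected


def make_layout(columns: list[str]):
    """Build a :class:`BitLayout` (regular grid) or :class:`RaggedLayout`."""
    residues, types = _layout_from_columns(columns)
    if _is_regular(columns, residues, types):
        return BitLayout(residues, types)
    return RaggedLayout(tuple(columns))


# ---------------------------------------------------------------------------
# I/O


def read_dataset(path, name: str | None = None) -> FingerprintDataset:
    """Read a fingerprint CSV/TSV (``ligand_id,active,RES:INT,...``).

    The delimiter is sniffed (comma or tab). Raises :class:`FormatError` for
    a malformed header and :class:`ValueError` for non-binary cells or
    inconsistent row lengths, naming the offending row/column.
    """
    with open(path, "r", newline="") as fh:
        text = fh.read()
    return _parse_dataset(text, name or str(path))


def _parse_dataset(text: str, name: str) -> FingerprintDataset:
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.reader(io.StringIO(text), delimiter=delimiter)
    try:
        header = next(reader)
    except StopIteration:
        raise FormatError("empty file") from None
    if len(header) < 3 or header[0] != "ligand_id" or header[1] != "active":
        raise FormatError(
            "header must start with 'ligand_id,active' followed by RES:INT columns"
        )
    layout = make_layout(header[2:])
    n_bits = len(layout)
    fps = []
    for row_no, row in enumerate(reader, start=2):
        if not row:
            continue
        if len(row) != n_bits + 2:
            raise ValueError(
                f"row {row_no}: expected {n_bits + 2} fields, got {len(row)}"
            )
        ligand_id = row[0]
        if row[1] not in ("0", "1"):
            raise ValueError(f"row {row_no}: activity must be 0 or 1, got {row[1]!r}")
        bits = np.empty(n_bits, dtype=np.uint8)
        for j, cell in enumerate(row[2:]):
            if cell not in ("0", "1"):
                raise ValueError(
                    f"row {row_no}, column {header[j + 2]!r}: "
                    f"bit must be 0 or 1, got {cell!r}"
                )
            bits[j] = cell == "1"
        fps.append(InteractionFingerprint(ligand_id, bits, row[1] == "1"))
    return _make_dataset(name, layout, fps)


def _make_dataset(name, layout, fps):
    if isinstance(layout, BitLayout):
        return FingerprintDataset(name, layout, tuple(fps))
    # ragged layouts reuse the container but skip grid validation via a
    # regular-grid check on explicit columns
    ds = FingerprintDataset.__new__(FingerprintDataset)
    object.__setattr__(ds, "name", name)
    object.__setattr__(ds, "layout", layout)
    object.__setattr__(ds, "fingerprints", tuple(fps))
    n = len(layout)
    for fp in fps:
        if len(fp) != n:
            raise ValueError(
                f"fingerprint {fp.ligand_id!r} has {len(fp)} bits, layout defines {n}"
            )
    return ds


def write_dataset(dataset: FingerprintDataset, path) -> None:
    """Write the comma-delimited fingerprint CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ligand_id", "active", *dataset.layout.columns])
        for fp in dataset.fingerprints:
            writer.writerow([fp.ligand_id, int(fp.active), *fp.bits.tolist()])


# ---------------------------------------------------------------------------
# bit selection and filtering


def select_bits(dataset: FingerprintDataset, scheme: str) -> FingerprintDataset:
    """Apply a bit-selection scheme: ``ALL``, ``WO1`` or ``WO3``.

    ``ALL`` is the identity; ``WO1`` drops every "Any contact" column; ``WO3``
    drops the "Any", backbone and sidechain contact columns. Residue order and
    the order of the remaining interaction types are preserved. Removing a
    type that is absent from the layout is a no-op.
    """
    if scheme not in BIT_SELECTIONS:
        raise ValueError(f"unknown bit-selection scheme {scheme!r}")
    dropped = BIT_SELECTIONS[scheme]
    if not dropped:
        return dataset
    keep = np.array(
        [c.split(":", 1)[1] not in dropped for c in dataset.layout.columns], dtype=bool
    )
    if keep.all():
        return dataset
    return _subset(dataset, keep)


def filter_residues(dataset: FingerprintDataset) -> FingerprintDataset:
    """Residue-based filtering (RES): drop every residue whose whole bit
    block is zero across all fingerprints in the dataset."""
    mask = residue_filter_mask(dataset)
    if not mask.any():
        raise ValueError("residue filtering removed every column")
    if mask.all():
        return dataset
    return _subset(dataset, mask)


def filter_interactions(dataset: FingerprintDataset) -> FingerprintDataset:
    """Interaction-based filtering (INTS): drop every individual column that
    is never set across the dataset (a superset of RES's removals)."""
    mask = interaction_filter_mask(dataset)
    if not mask.any():
        raise ValueError("interaction filtering removed every column")
    if mask.all():
        return dataset
    return _subset(dataset, mask)


def residue_filter_mask(dataset: FingerprintDataset) -> np.ndarray:
    """Boolean keep-mask for RES filtering."""
    if not len(dataset):
        raise ValueError("cannot filter an empty dataset")
    bits = dataset.bit_matrix
    n_types = len(dataset.layout.interaction_types)
    col_any = bits.any(axis=0)
    if isinstance(dataset.layout, BitLayout):
        per_res = col_any.reshape(-1, n_types).any(axis=1)
        return np.repeat(per_res, n_types)
    # ragged layout: group columns by residue name
    residues = [c.split(":", 1)[0] for c in dataset.layout.columns]
    alive = {r: False for r in residues}
    for r, on in zip(residues, col_any):
        alive[r] = alive[r] or bool(on)
    return np.array([alive[r] for r in residues], dtype=bool)


def interaction_filter_mask(dataset: FingerprintDataset) -> np.ndarray:
    """Boolean keep-mask for INTS filtering."""
    if not len(dataset):
        raise ValueError("cannot filter an empty dataset")
    return dataset.bit_matrix.any(axis=0)


def apply_filtering(dataset: FingerprintDataset, rule: str) -> FingerprintDataset:
    """Dispatch on a filtering rule name: ``NO``, ``RES`` or ``INTS``."""
    if rule == "NO":
        return dataset
    if rule == "RES":
        return filter_residues(dataset)
    if rule == "INTS":
        return filter_interactions(dataset)
    raise ValueError(f"unknown filtering rule {rule!r}")


def _subset(dataset: FingerprintDataset, keep: np.ndarray) -> FingerprintDataset:
    cols = [c for c, k in zip(dataset.layout.columns, keep) if k]
    layout = make_layout(cols)
    fps = [replace(fp, bits=fp.bits[keep]) for fp in dataset.fingerprints]
    return _make_dataset(dataset.name, layout, fps)


def conform_fingerprint(fp: InteractionFingerprint, source_layout, target_layout) -> InteractionFingerprint:
    """Project a fingerprint from ``source_layout`` onto ``target_layout``.

    Every column of the target layout must exist in the source layout; used
    to carry a reference fingerprint through bit selection and filtering that
    were computed on the query dataset.
    """
    src = {c: i for i, c in enumerate(source_layout.columns)}
    try:
        idx = np.array([src[c] for c in target_layout.columns], dtype=int)
    except KeyError as exc:
        raise ValueError(f"target column {exc.args[0]!r} absent from source layout") from None
    return replace(fp, bits=fp.bits[idx])
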