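"""Symbolic specification of structural equation models with mean structure.

A model is described by six parameter matrices in LISREL-style notation for
observed variables ``y`` and latent variables ``eta``::

    y   = nu + Lambda @ eta + eps,   eps  ~ N(0, Theta)
    eta = alpha + B @ eta + zeta,    zeta ~ N(0, Psi)

Each cell of each matrix is either *fixed* at a value or *free*.  Free cells
carry a label; cells sharing a label share one entry of the packed parameter
vector (this is how cross-reporter equality constraints are imposed).  Labels
are global across groups, so a multi-group model with shared labels pools
those parameters.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

MATRICES = ("lambda", "nu", "theta", "beta", "psi", "alpha")
_SYMMETRIC = {"theta", "psi"}
_LATENT_ROW = {"beta", "psi", "alpha"}
_VECTOR = {"nu", "alpha"}


class SpecError(ValueError):
    """Raised for malformed or unidentified model specifications."""


@dataclass(frozen=True)
class Cell:
    """One entry of a parameter matrix."""

    matrix: str
    row: str
    col: str | None
    free: bool
    value: float
    label: str | None

    @property
    def key(self) -> tuple[str, str, str | None]:
        return (self.matrix, self.row, self.col)


def _canon(matrix: str, row: str, col: str | None) -> tuple[str, str, str | None]:
    if matrix in _VECTOR:
        return (matrix, row, None)
    return (matrix, row, col)


class ModelSpec:
    """Single-group SEM specification over named variables.

    Parameters
    ----------
    observed:
        Ordered names of observed variables.
    latents:
        Ordered names of latent variables.

    Cells never mentioned are implicitly fixed at zero.  Symmetric matrices
    (``theta``, ``psi``) store each off-diagonal pair once; the (row, col)
    order used at insertion is preserved.
    """

    def __init__(self, observed: list[str], latents: list[str]):
        if len(set(observed)) != len(observed):
            raise SpecError("duplicate observed variable names")
        if len(set(latents)) != len(latents):
            raise SpecError("duplicate latent variable names")
        if set(observed) & set(latents):
            raise SpecError("observed and latent names must be disjoint")
        self.observed = list(observed)
        self.latents = list(latents)
        self._obs_ix = {v: i for i, v in enumerate(observed)}
        self._lat_ix = {v: i for i, v in enumerate(latents)}
        self._cells: dict[tuple[str, str, str | None], Cell] = {}

    # -- construction -----------------------------------------------------

    def add(
        self,
        matrix: str,
        row: str,
        col: str | None = None,
        *,
        free: bool = True,
        value: float = 0.0,
        label: str | None = None,
    ) -> "ModelSpec":
        """Declare one cell.  Returns self so calls can be chained."""
        if matrix not in MATRICES:
            raise SpecError(f"unknown matrix {matrix!r}")
        self._check_names(matrix, row, col)
        if matrix in _SYMMETRIC and col != row:
            mirror = _canon(matrix, col, row)  # type: ignore[arg-type]
            if mirror in self._cells:
                raise SpecError(f"{matrix}[{row},{col}] already declared as its mirror")
        cell = Cell(matrix, row, col if matrix not in _VECTOR else None, free, float(value), label)
        self._cells[cell.key] = cell
        return self

    def _check_names(self, matrix: str, row: str, col: str | None) -> None:
        if matrix == "lambda":
            if row not in self._obs_ix or col not in self._lat_ix:
                raise SpecError(f"lambda[{row},{col}]: need observed row, latent col")
        elif matrix == "nu":
            if row not in self._obs_ix:
                raise SpecError(f"nu[{row}]: unknown observed variable")
        elif matrix == "theta":
            if row not in self._obs_ix or col not in self._obs_ix:
                raise SpecError(f"theta[{row},{col}]: unknown observed variable")
        elif matrix in ("beta", "psi"):
            if row not in self._lat_ix or col not in self._lat_ix:
                raise SpecError(f"{matrix}[{row},{col}]: unknown latent variable")
        elif matrix == "alpha":
            if row not in self._lat_ix:
                raise SpecError(f"alpha[{row}]: unknown latent variable")

    def cells(self) -> list[Cell]:
        return list(self._cells.values())

    def get(self, matrix: str, row: str, col: str | None = None) -> Cell | None:
        return self._cells.get(_canon(matrix, row, col))

    def drop(self, matrix: str, row: str, col: str | None = None) -> None:
        self._cells.pop(_canon(matrix, row, col), None)

    def copy(self) -> "ModelSpec":
        out = ModelSpec(self.observed, self.latents)
        out._cells = dict(self._cells)
        return out

    def relabel(
        self, matrix: str, row: str, col: str | None = None, *, label: str | None = None,
        value: float | None = None,
    ) -> "ModelSpec":
        """Replace the label of an existing free cell (used to break equalities)."""
        cell = self.get(matrix, row, col)
        if cell is None:
            raise SpecError(f"no such cell {matrix}[{row},{col}]")
        self._cells[cell.key] = Cell(
            cell.matrix, cell.row, cell.col, cell.free,
            cell.value if value is None else float(value), label,
        )
        return self

    # -- bookkeeping ------------------------------------------------------

    @property
    def n_observed(self) -> int:
        return len(self.observed)

    @property
    def n_latent(self) -> int:
        return len(self.latents)

    def free_labels(self) -> list[str]:
        """Distinct parameter labels in declaration order (auto-named if absent)."""
        seen: list[str] = []
        for cell in self._cells.values():
            if cell.free:
                lab = cell.label or _auto_label(cell)
                if lab not in seen:
                    seen.append(lab)
        return seen

    # -- serialization ----------------------------------------------------

    def to_text(self) -> str:
        """One line per declared cell: matrix row col kind value label."""
        buf = io.StringIO()
        buf.write("observed: " + " ".join(self.observed) + "\n")
        buf.write("latents: " + " ".join(self.latents) + "\n")
        for cell in self._cells.values():
            kind = "free" if cell.free else "fixed"
            col = cell.col if cell.col is not None else "-"
            lab = cell.label if cell.label is not None else "-"
            buf.write(f"{cell.matrix} {cell.row} {col} {kind} {cell.value:.10g} {lab}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "ModelSpec":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        if not lines[0].startswith("observed:") or not lines[1].startswith("latents:"):
            raise SpecError("malformed spec text header")
        observed = lines[0].split(":", 1)[1].split()
        latents = lines[1].split(":", 1)[1].split()
        spec = cls(observed, latents)
        for ln in lines[2:]:
            matrix, row, col, kind, value, lab = ln.split()
            spec.add(
                matrix, row, None if col == "-" else col,
                free=(kind == "free"), value=float(value),
                label=None if lab == "-" else lab,
            )
        return spec


def _auto_label(cell: Cell) -> str:
    col = cell.col if cell.col is not None else ""
    return f".{cell.matrix}.{cell.row}.{col}"


@dataclass
class GroupModel:
    """A fitted-model ingredient: one group's spec plus index maps into theta."""

    spec: ModelSpec
    # per matrix: (row_idx, col_idx, theta_idx) for free cells and
    # (row_idx, col_idx, value) for fixed nonzero cells
    free_cells: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)
    fixed_cells: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)


class ParamIndex:
    """Packs the free parameters of one or more group specs into one vector.

    Labels shared across groups map to the same vector entry; unlabeled free
    cells get group-local auto labels.
    """

    def __init__(self, specs: list[ModelSpec]):
        self.specs = specs
        self.labels: list[str] = []
        self._label_ix: dict[str, int] = {}
        self.start: np.ndarray
        self.groups: list[GroupModel] = []
        starts: dict[str, float] = {}
        for g, spec in enumerate(specs):
            gm = GroupModel(spec, {m: [] for m in MATRICES}, {m: [] for m in MATRICES})
            for cell in spec.cells():
                r, c = _cell_indices(spec, cell)
                if cell.free:
                    lab = cell.label or f"g{g}{_auto_label(cell)}"
                    if lab not in self._label_ix:
                        self._label_ix[lab] = len(self.labels)
                        self.labels.append(lab)
                        starts[lab] = cell.value
                    gm.free_cells[cell.matrix].append((r, c, self._label_ix[lab]))
                elif cell.value != 0.0:
                    gm.fixed_cells[cell.matrix].append((r, c, cell.value))
            self.groups.append(gm)
        self.start = np.array([starts[lab] for lab in self.labels], dtype=float)

    @property
    def n_free(self) -> int:
        return len(self.labels)

    def label_of(self, group: int, matrix: str, row: str, col: str | None = None) -> str | None:
        cell = self.specs[group].get(matrix, row, col)
        if cell is None or not cell.free:
            return None
        return cell.label or f"g{group}{_auto_label(cell)}"

    def theta_index(self, group: int, matrix: str, row: str, col: str | None = None) -> int:
        lab = self.label_of(group, matrix, row, col)
        if lab is None:
            raise SpecError(f"{matrix}[{row},{col}] is not free in group {group}")
        return self._label_ix[lab]

    def variance_bounds(self, floor: float = 1e-6) -> list[tuple[float | None, float | None]]:
        """Lower bounds for variance parameters (diagonal theta/psi cells)."""
        bounds: list[tuple[float | None, float | None]] = [(None, None)] * self.n_free
        for g, gm in enumerate(self.groups):
            for matrix in ("theta", "psi"):
                for r, c, j in gm.free_cells[matrix]:
                    if r == c:
                        bounds[j] = (floor, None)
        return bounds

    def matrices(self, group: int, theta: np.ndarray) -> dict[str, np.ndarray]:
        """Materialize the six numeric matrices for one group at ``theta``."""
        spec = self.specs[group]
        p, m = spec.n_observed, spec.n_latent
        shapes = {
            "lambda": (p, m), "nu": (p,), "theta": (p, p),
            "beta": (m, m), "psi": (m, m), "alpha": (m,),
        }
        out = {name: np.zeros(shape) for name, shape in shapes.items()}
        gm = self.groups[group]
        for matrix in MATRICES:
            arr = out[matrix]
            for r, c, v in gm.fixed_cells[matrix]:
                _assign(arr, matrix, r, c, v)
            for r, c, j in gm.free_cells[matrix]:
                _assign(arr, matrix, r, c, theta[j])
        return out


def _cell_indices(spec: ModelSpec, cell: Cell) -> tuple[int, int]:
    if cell.matrix == "lambda":
        return spec._obs_ix[cell.row], spec._lat_ix[cell.col]  # type: ignore[index]
    if cell.matrix == "nu":
        return spec._obs_ix[cell.row], 0
    if cell.matrix == "theta":
        return spec._obs_ix[cell.row], spec._obs_ix[cell.col]  # type: ignore[index]
    if cell.matrix in ("beta", "psi"):
        return spec._lat_ix[cell.row], spec._lat_ix[cell.col]  # type: ignore[index]
    return spec._lat_ix[cell.row], 0


def _assign(arr: np.ndarray, matrix: str, r: int, c: int, v: float) -> None:
    if arr.ndim == 1:
        arr[r] = v
    elif matrix in _SYMMETRIC:
        arr[r, c] = v
        arr[c, r] = v
    else:
        arr[r, c] = v
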