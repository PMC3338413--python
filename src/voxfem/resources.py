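"""Analytic memory and cost models for the element-by-element solver.

These are pure arithmetic models of the single-precision production
storage scheme — they never measure the running process.  Per element, the
element-by-element (EBE) method stores the bone-volume fraction (1 byte),
compressed vertex-variable base indices (16 bytes: 24 indices x 4 bytes,
of which only one sixth need storing thanks to the direction-innermost
numbering), the five CG work vectors plus the Jacobi preconditioner
(4 bytes x 5 x N_v), and a 4-byte-per-vertex variable lookup map.  With
the empirical N_v ~ 4 N_e and a 1/8-occupancy bound on the lookup map the
total is ~130 bytes/element, about a factor of 10 below explicit sparse
storage (up to 81 nonzeros x 4 bytes = 324 bytes per variable, i.e. 1296
bytes per element).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ResourceEstimate",
    "ebe_memory_model",
    "full_matrix_memory_model",
    "multiplication_ratio",
    "overhead_fraction",
]

#: Default empirical ratio of free variables to elements for trabecular
#: structures (3 for a fully occupied volume, closer to 4 with boundary
#: vertices and sparse occupancy).
DEFAULT_NV_PER_ELEMENT = 4.0

_BYTES_BVF = 1
_BYTES_INDEX = 16  # (24 x 4) / 6
_BYTES_PER_VECTOR_ENTRY = 4  # single-precision production accounting
_N_CG_VECTORS = 5  # u, r, p, q, preconditioner
_LOOKUP_BOUND = 32  # 4 bytes/vertex at >= 1/8 voxel occupancy
_SPARSE_ROW_ENTRIES = 81  # 27 neighbor vertices x 3 directions
_EBE_MULTS_PER_ELEMENT = 24 * 24


def overhead_fraction(K: int, n_z: int) -> float:
    """Interface-duplication memory overhead of K Z-slab sub-regions.

    Each of the K-1 internal interfaces duplicates two vertex layers:
    ``2 (K - 1) / N_z``.
    """
    if not (1 <= K <= n_z):
        raise ValueError("need 1 <= K <= N_z")
    return 2.0 * (K - 1) / n_z


@dataclass(frozen=True)
class ResourceEstimate:
    """Component-wise byte counts of the EBE storage scheme."""

    components: dict[str, float]
    overhead: float
    n_elements: int

    @property
    def total_bytes(self) -> float:
        return sum(self.components.values()) * (1.0 + self.overhead)

    @property
    def bytes_per_element(self) -> float:
        return self.total_bytes / self.n_elements

    def bytes_per_element_rounded(self) -> int:
        """Per-element total rounded to the nearest ten bytes."""
        return int(round(self.bytes_per_element / 10.0)) * 10

    def table(self) -> str:
        lines = [f"{'component':<28}{'bytes':>16}"]
        for name, b in self.components.items():
            lines.append(f"{name:<28}{b:>16,.0f}")
        lines.append(f"{'interface overhead':<28}{self.overhead:>15.1%}")
        lines.append(f"{'total':<28}{self.total_bytes:>16,.0f}")
        lines.append(
            f"{'per element':<28}{self.bytes_per_element_rounded():>14d} B"
        )
        return "\n".join(lines)


def ebe_memory_model(
    n_elements: int,
    n_variables: float | None = None,
    dims: tuple[int, int, int] | None = None,
    K: int = 1,
    n_z: int | None = None,
) -> ResourceEstimate:
    """Expected memory of the element-by-element method.

    ``n_variables`` defaults to ``4 * n_elements``; the lookup map uses
    the actual image dimensions when given, otherwise the 32 bytes/element
    occupancy bound.  For K > 1 the total is scaled by the interface
    duplication overhead (N_z taken from ``dims``, ``n_z``, or a
    cubic-volume estimate ``n_elements ** (1/3)``).
    """
    if n_elements <= 0:
        raise ValueError("n_elements must be positive")
    nv = DEFAULT_NV_PER_ELEMENT * n_elements if n_variables is None else n_variables
    if nv <= 0:
        raise ValueError("n_variables must be positive")
    lookup = (
        4.0 * dims[0] * dims[1] * dims[2] if dims is not None else _LOOKUP_BOUND * n_elements
    )
    components = {
        "bone volume fraction": float(_BYTES_BVF * n_elements),
        "vertex-variable indices": float(_BYTES_INDEX * n_elements),
        "CG vectors + preconditioner": float(_BYTES_PER_VECTOR_ENTRY * _N_CG_VECTORS * nv),
        "variable lookup map": float(lookup),
    }
    if n_z is None:
        n_z = dims[2] if dims is not None else max(int(round(n_elements ** (1.0 / 3.0))), K)
    return ResourceEstimate(
        components=components,
        overhead=overhead_fraction(K, n_z),
        n_elements=n_elements,
    )


def full_matrix_memory_model(n_elements: int, n_variables: float | None = None) -> float:
    """Bytes needed to store A explicitly in a sparse scheme (upper bound).

    Up to 81 entries x 4 bytes = 324 bytes per variable; with
    ``N_v = 4 N_e`` this is 1296 bytes per element (entry locations not
    even counted).
    """
    if n_elements <= 0:
        raise ValueError("n_elements must be positive")
    nv = DEFAULT_NV_PER_ELEMENT * n_elements if n_variables is None else n_variables
    return _SPARSE_ROW_ENTRIES * _BYTES_PER_VECTOR_ENTRY * nv


def multiplication_ratio(nv_per_element: float = DEFAULT_NV_PER_ELEMENT) -> float:
    """EBE / sparse multiplication count per iteration, one decimal.

    EBE performs 24^2 multiplications per element; a sparse matrix-vector
    product performs up to 81 per variable.
    """
    if nv_per_element <= 0:
        raise ValueError("nv_per_element must be positive")
    ratio = _EBE_MULTS_PER_ELEMENT / (_SPARSE_ROW_ENTRIES * nv_per_element)
    return round(ratio, 1)
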