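"""Region adjacency structures, CAR quadratic forms and standardized prevalence.

The spatial backbone of the package: an undirected contiguity graph over the
study regions.  Intrinsic conditional-autoregressive (CAR) priors are defined
through the pairwise-difference quadratic form on this graph, and standardized
prevalence ratios (SPR) are computed from internally standardized expected
counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "RegionMap",
    "StandardizedCounts",
    "build_region_map",
    "read_adjacency",
    "car_quadratic_form",
    "expected_counts",
    "spr",
    "read_regional_table",
    "write_regional_table",
]

GENDERS = ("male", "female")


@dataclass(frozen=True)
class RegionMap:
    """Ordered region labels plus a symmetric, self-loop-free adjacency.

    ``regions`` fixes the index order used by every vectorized structure in
    the package.  ``edges`` holds unordered label pairs stored with the
    lower-index label first.
    """

    regions: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "index", {r: i for i, r in enumerate(self.regions)}
        )

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def neighbor_counts(self) -> dict[str, int]:
        counts = {r: 0 for r in self.regions}
        for a, b in self.edges:
            counts[a] += 1
            counts[b] += 1
        return counts

    def neighbors(self, region: str) -> list[str]:
        out = []
        for a, b in self.edges:
            if a == region:
                out.append(b)
            elif b == region:
                out.append(a)
        return sorted(out, key=self.index.__getitem__)

    def adjacency_matrix(self) -> np.ndarray:
        """Dense binary (0/1) adjacency in region order."""
        n = self.n_regions
        w = np.zeros((n, n))
        for a, b in self.edges:
            i, j = self.index[a], self.index[b]
            w[i, j] = w[j, i] = 1.0
        return w

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian ``D - W`` (the intrinsic-CAR precision shape)."""
        w = self.adjacency_matrix()
        return np.diag(w.sum(axis=1)) - w

    def neighbor_index_lists(self) -> list[np.ndarray]:
        """Per-region integer arrays of neighbor indices (sampler hot path)."""
        nbrs: list[list[int]] = [[] for _ in self.regions]
        for a, b in self.edges:
            i, j = self.index[a], self.index[b]
            nbrs[i].append(j)
            nbrs[j].append(i)
        return [np.array(sorted(v), dtype=np.intp) for v in nbrs]

    def component_labels(self) -> np.ndarray:
        """Connected-component label per region (intrinsic-CAR rank bookkeeping)."""
        n = self.n_regions
        w = csr_matrix(self.adjacency_matrix())
        _, labels = connected_components(w, directed=False)
        return labels if n else np.zeros(0, dtype=int)

    @property
    def n_components(self) -> int:
        return int(self.component_labels().max()) + 1 if self.regions else 0

    def drop(self, excluded: Iterable[str]) -> "RegionMap":
        """Return a new map with ``excluded`` regions (and their edges) removed."""
        excluded = set(excluded)
        unknown = excluded - set(self.regions)
        if unknown:
            raise ValueError(f"unknown region(s) to exclude: {sorted(unknown)}")
        keep = tuple(r for r in self.regions if r not in excluded)
        edges = frozenset(
            e for e in self.edges if e[0] not in excluded and e[1] not in excluded
        )
        return build_region_map(keep, edges)


def build_region_map(
    regions: Sequence[str], edges: Iterable[tuple[str, str]]
) -> RegionMap:
    """Validate and canonicalize an adjacency into a :class:`RegionMap`.

    Edges are deduplicated and stored unordered; self-edges and edges touching
    undeclared labels are input errors.  Isolated regions are legal but
    flagged with a warning because intrinsic-CAR smoothing cannot reach them.
    """
    regions = tuple(str(r) for r in regions)
    if len(set(regions)) != len(regions):
        raise ValueError("region labels must be unique")
    declared = set(regions)
    order = {r: i for i, r in enumerate(regions)}
    canon = set()
    for a, b in edges:
        a, b = str(a), str(b)
        if a == b:
            raise ValueError(f"self-edge on region {a!r}")
        for lbl in (a, b):
            if lbl not in declared:
                raise ValueError(f"edge endpoint {lbl!r} is not a declared region")
        canon.add((a, b) if order[a] < order[b] else (b, a))
    rmap = RegionMap(regions, frozenset(canon))
    isolated = [r for r, c in rmap.neighbor_counts.items() if c == 0]
    if isolated:
        warnings.warn(
            f"isolated region(s) with no neighbors: {isolated}", stacklevel=2
        )
    return rmap


def read_adjacency(path) -> RegionMap:
    """Read a two-column edge-list file ('#' comments) into a RegionMap.

    Region order is first-appearance order in the file; an optional
    ``# regions: a,b,c`` header line pins the order (and admits isolated
    regions) explicitly.
    """
    regions: list[str] = []
    seen = set()
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("regions:"):
                    for lbl in body.split(":", 1)[1].split(","):
                        lbl = lbl.strip()
                        if lbl and lbl not in seen:
                            regions.append(lbl)
                            seen.add(lbl)
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"malformed adjacency line: {line!r}")
            for lbl in parts:
                if lbl not in seen:
                    regions.append(lbl)
                    seen.add(lbl)
            edges.append((parts[0], parts[1]))
    if not regions:
        raise ValueError(f"no regions found in adjacency file {path}")
    return build_region_map(regions, edges)


def car_quadratic_form(values: Mapping[str, float] | np.ndarray, rmap: RegionMap) -> float:
    """Sum of squared differences over unordered neighbor pairs.

    This is the quadratic form inside every intrinsic-CAR log density,
    ``sum_{i~j, i<j} (v_i - v_j)^2``; equivalently ``v' L v`` with ``L`` the
    graph Laplacian.  Invariant under adding a constant per connected
    component and zero iff the values are constant on each component.
    """
    if isinstance(values, Mapping):
        missing = [r for r in rmap.regions if r not in values]
        if missing:
            raise ValueError(f"missing values for region(s): {missing}")
        v = np.array([float(values[r]) for r in rmap.regions])
    else:
        v = np.asarray(values, dtype=float)
        if v.shape != (rmap.n_regions,):
            raise ValueError(
                f"expected {rmap.n_regions} values, got shape {v.shape}"
            )
    total = 0.0
    for a, b in rmap.edges:
        d = v[rmap.index[a]] - v[rmap.index[b]]
        total += d * d
    return float(total)


@dataclass(frozen=True)
class StandardizedCounts:
    """Observed and internally standardized expected counts per (gender, region)."""

    observed: dict[tuple[str, str], int]
    expected: dict[tuple[str, str], float]

    def genders(self) -> list[str]:
        return sorted({g for g, _ in self.observed}, key=lambda g: GENDERS.index(g))


def expected_counts(data) -> StandardizedCounts:
    """Expected counts by crude internal standardization, per gender.

    ``E[j,i] = n[j,i] * (sum_i O[j,i] / sum_i n[j,i])`` so that, within each
    gender, the expected counts sum exactly to the observed ones.  ``data``
    is an :class:`scmap.model.SCMData` (duck-typed: needs ``region_map``,
    ``O`` and ``n`` arrays in region order).
    """
    observed: dict[tuple[str, str], int] = {}
    expected: dict[tuple[str, str], float] = {}
    for j, gender in enumerate(GENDERS[: data.O.shape[0]]):
        tot_n = float(data.n[j].sum())
        if tot_n <= 0:
            raise ValueError(f"zero total denominator for gender {gender!r}")
        rate = float(data.O[j].sum()) / tot_n
        for i, region in enumerate(data.region_map.regions):
            observed[(gender, region)] = int(data.O[j, i])
            expected[(gender, region)] = float(data.n[j, i]) * rate
    return StandardizedCounts(observed, expected)


def spr(counts: StandardizedCounts) -> dict[tuple[str, str], float]:
    """Standardized prevalence ratio, observed over expected count per cell.

    The E-weighted mean SPR within each gender is 1 by construction of the
    internal standardization (mass conservation).
    """
    out = {}
    for key, e in counts.expected.items():
        if e <= 0:
            raise ZeroDivisionError(
                f"expected count is zero for (gender, region) = {key}"
            )
        out[key] = counts.observed[key] / e
    return out


# ---------------------------------------------------------------------------
# Regional-table text I/O (region, gender, cases, n, covariate columns)

def read_regional_table(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    required = {"region", "gender", "cases", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"regional table missing column(s): {sorted(missing)}")
    if (df["cases"] > df["n"]).any():
        bad = df.loc[df["cases"] > df["n"], "region"].tolist()
        raise ValueError(f"cases exceed denominators in region(s): {bad}")
    return df


def write_regional_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False)
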