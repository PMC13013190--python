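"""3D lattice geometry and occupancy bookkeeping.

Agents live on a regular 3D grid with at most one agent per site.  The
neighbourhood is the Moore neighbourhood (26 sites in the interior);
boundary sites have clipped, non-periodic neighbourhoods.  Coordinates are
0-based; extents are exclusive upper bounds.  Neighbour ordering is
deterministic (lexicographic by offset) so that random-number consumption
is reproducible for a fixed seed.
"""

from __future__ import annotations

import itertools
from typing import Callable, Iterable

import numpy as np

#: A lattice site: integer (x, y, z) coordinates.
Site = tuple[int, int, int]

# Lexicographically ordered Moore offsets, centre excluded.
MOORE_OFFSETS: tuple[Site, ...] = tuple(
    off for off in itertools.product((-1, 0, 1), repeat=3) if off != (0, 0, 0)
)


class BoundsError(IndexError):
    """A site lies outside the lattice extents."""


class OccupancyError(ValueError):
    """An occupancy operation would violate the one-agent-per-site rule."""


class Lattice:
    """A bounded 3D grid with single-occupancy bookkeeping.

    Parameters
    ----------
    extents
        Three positive integers (nx, ny, nz); valid coordinates are
        ``0 <= x < nx`` etc.
    """

    def __init__(self, extents: Iterable[int]):
        ext = tuple(int(e) for e in extents)
        if len(ext) != 3 or any(e <= 0 for e in ext):
            raise ValueError(f"extents must be 3 positive integers, got {ext}")
        self.extents: Site = ext  # type: ignore[assignment]
        self._occupancy: dict[Site, int] = {}
        # boolean mirror of the occupancy map for vectorised queries
        self.occupancy_mask = np.zeros(ext, dtype=bool)

    # -- geometry ----------------------------------------------------------

    def in_bounds(self, site: Site) -> bool:
        return all(0 <= c < e for c, e in zip(site, self.extents))

    def _check_bounds(self, site: Site) -> None:
        if not self.in_bounds(site):
            raise BoundsError(f"site {site} outside extents {self.extents}")

    def neighbors(self, site: Site) -> list[Site]:
        """All in-bounds Moore neighbours of ``site`` (site itself excluded).

        Interior sites have 26 neighbours; sites on 1/2/3 boundary planes
        have 17/11/7.  Order is deterministic (lexicographic by offset).
        """
        self._check_bounds(site)
        x, y, z = site
        nx, ny, nz = self.extents
        out = []
        for dx, dy, dz in MOORE_OFFSETS:
            p = (x + dx, y + dy, z + dz)
            if 0 <= p[0] < nx and 0 <= p[1] < ny and 0 <= p[2] < nz:
                out.append(p)
        return out

    def free_neighbors(self, site: Site) -> list[Site]:
        """The unoccupied subset of :meth:`neighbors` (may be empty)."""
        occ = self._occupancy
        return [p for p in self.neighbors(site) if p not in occ]

    # -- occupancy ---------------------------------------------------------

    def is_free(self, site: Site) -> bool:
        self._check_bounds(site)
        return site not in self._occupancy

    def occupant(self, site: Site) -> int | None:
        """Agent id at ``site``, or None if free."""
        self._check_bounds(site)
        return self._occupancy.get(site)

    def place(self, site: Site, agent_id: int) -> None:
        self._check_bounds(site)
        if site in self._occupancy:
            raise OccupancyError(f"site {site} already occupied")
        self._occupancy[site] = agent_id
        self.occupancy_mask[site] = True

    def remove(self, site: Site) -> int:
        self._check_bounds(site)
        try:
            agent = self._occupancy.pop(site)
        except KeyError:
            raise OccupancyError(f"site {site} is not occupied") from None
        self.occupancy_mask[site] = False
        return agent

    def move(self, src: Site, dst: Site) -> None:
        agent = self.remove(src)
        self.place(dst, agent)

    @property
    def n_occupied(self) -> int:
        return len(self._occupancy)

    def occupied_sites(self) -> list[Site]:
        return list(self._occupancy)

    def random_free_site(self, rng: np.random.Generator, max_tries: int = 10_000) -> Site | None:
        """Uniformly random free site, or None if the lattice is full.

        Rejection sampling; falls back to an exhaustive scan when the
        lattice is nearly saturated.
        """
        nx, ny, nz = self.extents
        total = nx * ny * nz
        if len(self._occupancy) >= total:
            return None
        for _ in range(max_tries):
            s = (int(rng.integers(nx)), int(rng.integers(ny)), int(rng.integers(nz)))
            if s not in self._occupancy:
                return s
        free = [s for s in itertools.product(range(nx), range(ny), range(nz))
                if s not in self._occupancy]
        return free[int(rng.integers(len(free)))]


def distance_to_nearest(
    site: Site,
    targets: Iterable[Site] | np.ndarray,
    metric: str | Callable[[np.ndarray], np.ndarray] = "euclidean",
) -> float:
    """Minimum distance from ``site`` to any target site.

    ``targets`` may be any iterable of sites or an (n, 3) integer array.
    The default metric is Euclidean on lattice indices; ``metric`` may also
    be a callable mapping an (n, 3) array of coordinate differences to an
    (n,) array of distances.
    """
    arr = np.asarray(targets if isinstance(targets, np.ndarray) else list(targets))
    if arr.size == 0:
        raise ValueError("targets must be nonempty")
    diff = arr.reshape(-1, 3) - np.asarray(site)
    if callable(metric):
        d = metric(diff)
    elif metric == "euclidean":
        d = np.sqrt((diff * diff).sum(axis=1))
    elif metric == "chebyshev":
        d = np.abs(diff).max(axis=1)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return float(np.min(d))
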