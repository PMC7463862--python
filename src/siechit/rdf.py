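"""Radial distribution function and distance-criterion hydrogen bonds.

The RDF g(r) between two atom selections histograms all cross-pair
distances over trajectory frames. "shell-volume" normalization divides by
the spherical-shell volume 4 pi r^2 dr and by the mean pair density within
the r_max sphere, so an ideal gas gives g ~ 1; "counts-only" returns the
probability-density histogram (integrates to 1). The RDF peak position
localizes a persistent contact such as the Asp carboxylate -
GlcNAc-amide-nitrogen hydrogen bond; hydrogen bonding itself is scored by
a pure distance criterion (default cutoff 3.0 A, no angle term).

Complexes are treated as compact (no minimum-image convention); an
orthorhombic periodic mode exists for ideal-gas validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atoms import AtomSelection, SelectionError, Trajectory

__all__ = [
    "RDFProfile",
    "HBondReport",
    "radial_distribution",
    "rdf_peak",
    "hbond_occupancy",
]


@dataclass(frozen=True)
class RDFProfile:
    bin_edges: np.ndarray       # A, len = n_bins + 1
    g: np.ndarray               # dimensionless, len = n_bins
    raw_counts: np.ndarray      # pair counts per bin summed over frames
    n_frames: int
    n_pairs: int                # cross pairs per frame
    normalization: str          # "shell-volume" | "counts-only"

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class HBondReport:
    cutoff: float               # A
    per_frame: np.ndarray       # bool, any donor-acceptor pair <= cutoff
    occupancy: float            # fraction of frames
    min_distance: np.ndarray    # A, per-frame minimum cross-pair distance


def _pair_setup(sel_a: AtomSelection, sel_b: AtomSelection) -> tuple[bool, int]:
    """Validate the selection pair; returns (self_rdf, n_pairs)."""
    if sel_a.system is not sel_b.system:
        raise SelectionError("selections must address the same system")
    ia, ib = set(sel_a.indices.tolist()), set(sel_b.indices.tolist())
    if ia == ib:
        n = len(sel_a)
        if n < 2:
            raise SelectionError("self-RDF needs at least two atoms")
        return True, n * (n - 1)
    if ia & ib:
        raise SelectionError(
            "selections must be disjoint or identical (partial overlap)"
        )
    return False, len(sel_a) * len(sel_b)


def _cross_distances(
    a: np.ndarray, b: np.ndarray, self_pairs: bool, box: np.ndarray | None,
    chunk: int = 512,
) -> np.ndarray:
    """Flat array of cross-pair distances (excluding i==j for self pairs),
    minimum-image if an orthorhombic box is given. Chunked over rows to
    bound memory for large selections."""
    out = []
    for start in range(0, len(a), chunk):
        da = a[start:start + chunk]
        diff = da[:, None, :] - b[None, :, :]
        if box is not None:
            diff -= box * np.round(diff / box)
        d = np.sqrt(np.sum(diff * diff, axis=2))
        if self_pairs:
            for row in range(len(da)):
                d[row, start + row] = np.inf  # exclude self pair
        out.append(d.ravel())
    dist = np.concatenate(out)
    return dist[np.isfinite(dist)]


def radial_distribution(
    traj: Trajectory,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    bin_width: float = 0.05,
    r_max: float = 8.0,
    normalization: str = "shell-volume",
    box: np.ndarray | None = None,
) -> RDFProfile:
    """Binned pair-distance distribution g(r) over all trajectory frames."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if r_max <= bin_width:
        raise ValueError("r_max must exceed bin_width")
    if normalization not in ("shell-volume", "counts-only"):
        raise ValueError(f"unknown normalization {normalization!r}")
    self_rdf, n_pairs = _pair_setup(sel_a, sel_b)
    if box is not None:
        box = np.asarray(box, dtype=float)

    n_bins = int(np.ceil(r_max / bin_width))
    edges = bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for frame in traj.frames:
        d = _cross_distances(sel_a.coords(frame), sel_b.coords(frame), self_rdf, box)
        hist, _ = np.histogram(d, bins=edges)
        counts += hist

    total = counts.sum()
    if normalization == "counts-only":
        g = counts / (total * bin_width) if total > 0 else np.zeros(n_bins)
    else:
        shell = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        sphere = (4.0 / 3.0) * np.pi * edges[-1] ** 3
        pair_density = total / (traj.n_frames * sphere)
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(
                (shell > 0) & (pair_density > 0),
                counts / (traj.n_frames * pair_density * shell),
                0.0,
            )
    return RDFProfile(
        bin_edges=edges,
        g=g,
        raw_counts=counts,
        n_frames=traj.n_frames,
        n_pairs=n_pairs,
        normalization=normalization,
    )


def rdf_peak(profile: RDFProfile) -> float:
    """Center of the bin with maximal g; ties break toward smaller r."""
    if not np.any(profile.g > 0):
        raise ValueError("all-zero RDF profile has no peak")
    return float(profile.bin_centers[int(np.argmax(profile.g))])


def hbond_occupancy(
    traj: Trajectory,
    donors: AtomSelection,
    acceptors: AtomSelection,
    cutoff: float = 3.0,
) -> HBondReport:
    """Distance-only hydrogen-bond criterion: a frame counts as bonded when
    any donor-acceptor pair is within ``cutoff`` Angstrom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    self_pairs, _ = _pair_setup(donors, acceptors)
    mins = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        d = _cross_distances(donors.coords(frame), acceptors.coords(frame), self_pairs, None)
        mins[i] = d.min()
    flags = mins <= cutoff
    return HBondReport(
        cutoff=cutoff,
        per_frame=flags,
        occupancy=float(flags.mean()),
        min_distance=mins,
    )
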