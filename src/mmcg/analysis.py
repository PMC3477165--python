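"""Trajectory observables: RMSD, per-residue RMSF, velocity autocorrelation,
O-O radial distribution and named-pair distance time series.

RMSD and (optionally) RMSF superpose each frame onto the reference with the
Kabsch algorithm before measuring, so global rigid motion never contributes.
The VACF is averaged over atoms and all time origins via FFT and normalized
to C(0) = 1; the decorrelation time is the lag beyond which |C(t)| stays
at its noise floor (see vacf_decorrelation_time).  The droplet system is not
periodic, so the RDF normalizes the pair histogram with the instantaneous
density taken from the convex-hull volume of the oxygen cloud.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.transform import Rotation

from .structure_io import Structure, Trajectory

__all__ = [
    "TimeSeries",
    "rmsd",
    "rmsf",
    "vacf",
    "vacf_decorrelation_time",
    "rdf_oo",
    "pair_distances",
    "kabsch_superpose",
]


@dataclass
class TimeSeries:
    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values differ in length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rigid superposition of ``mobile`` onto ``reference``."""
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(rc, mc)
    return rot.apply(mc) + reference.mean(axis=0)


def _resolve_selection(structure: Structure, selection) -> np.ndarray:
    """Selection: None (all), boolean mask, index array, or an atom-name
    list such as ["CA"]."""
    if selection is None:
        return np.arange(structure.n_atoms)
    selection = np.asarray(selection)
    if selection.dtype == bool:
        return np.flatnonzero(selection)
    if selection.dtype.kind in "iu":
        return selection.astype(int)
    idx = np.flatnonzero(np.isin(structure.name, selection))
    if len(idx) == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    return idx


def rmsd(trajectory: Trajectory, reference: np.ndarray | None = None,
         selection=None) -> TimeSeries:
    """Per-frame RMSD (nm) over the selection after Kabsch superposition."""
    sel = _resolve_selection(trajectory.structure, selection)
    ref = trajectory.structure.coords if reference is None else reference
    ref_sel = ref[sel]
    values = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        moved = kabsch_superpose(trajectory.coords[f][sel], ref_sel)
        values[f] = np.sqrt(np.mean(np.sum((moved - ref_sel) ** 2, axis=1)))
    return TimeSeries(trajectory.times, values, "RMSD (nm)")


def rmsf(trajectory: Trajectory, selection=None, align: bool = True):
    """Per-residue RMSF (nm) about the time-mean positions.

    Frames are optionally superposed on the first frame (over the
    selection) first; per-atom fluctuations are then averaged over each
    residue's selected (backbone) atoms.  Returns (residue_keys, values).
    """
    if trajectory.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    structure = trajectory.structure
    sel = _resolve_selection(structure, selection)
    coords = trajectory.coords[:, sel, :].copy()
    if align:
        for f in range(len(coords)):
            coords[f] = kabsch_superpose(coords[f], trajectory.coords[0][sel])
    mean = coords.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))

    keys, values = [], []
    res_of = [(str(structure.chain_id[i]), int(structure.res_id[i])) for i in sel]
    order: dict = {}
    for k, v in zip(res_of, per_atom):
        order.setdefault(k, []).append(v)
    for k, vals in order.items():
        keys.append(k)
        values.append(float(np.mean(vals)))
    return keys, np.array(values)


def vacf(velocities: np.ndarray, times: np.ndarray, selection=None,
         max_lag: float | None = None, structure: Structure | None = None,
         remove_com: bool = False) -> TimeSeries:
    """Normalized velocity autocorrelation C(t) averaged over atoms and all
    time origins (FFT accelerated); C(0) = 1 exactly.

    ``velocities``: (n_frames, n_atoms, 3) at a uniform sampling interval.
    ``remove_com`` subtracts the selection's mean velocity per frame, so a
    collective drift/oscillation of a confined droplet does not masquerade
    as single-particle correlation.
    """
    times = np.asarray(times, dtype=float)
    if len(times) > 2 and not np.allclose(np.diff(times), times[1] - times[0],
                                          rtol=1e-6, atol=1e-9):
        raise ValueError("velocity frames must be uniformly spaced")
    v = np.asarray(velocities, dtype=float)
    if selection is not None:
        sel = (_resolve_selection(structure, selection) if structure is not None
               else np.asarray(selection, dtype=int))
        v = v[:, sel, :]
    if remove_com:
        v = v - v.mean(axis=1, keepdims=True)
    n_frames = v.shape[0]
    dt = times[1] - times[0] if n_frames > 1 else 0.0
    n_lags = n_frames if max_lag is None else min(
        n_frames, int(round(max_lag / dt)) + 1)

    # autocorrelation via FFT over the time axis, summed over atoms/components
    nfft = 1 << int(np.ceil(np.log2(2 * n_frames)))
    spec = np.fft.rfft(v, n=nfft, axis=0)
    acf = np.fft.irfft(spec * np.conj(spec), n=nfft, axis=0)[:n_lags]
    acf = acf.sum(axis=(1, 2))
    counts = n_frames - np.arange(n_lags)   # origins per lag
    acf /= counts
    c = acf / acf[0]
    return TimeSeries(np.arange(n_lags) * dt, c, "VACF")


def vacf_decorrelation_time(series: TimeSeries, threshold: float = 0.02,
                            smooth_window: float = 0.05) -> float:
    """Time after which the velocity correlation is lost (ps).

    Reported as the first lag beyond which the smoothed |C(t)| stays
    below ``threshold`` for the rest of the computed window.  A liquid-
    water VACF crosses zero within ~0.2 ps and then oscillates (the cage
    dip), so a first-zero-crossing rule would answer a different
    question; "lost" means the curve has flattened to the level at which
    a plotted correlation function reads as zero (default 2% of C(0)).
    Smoothing over ``smooth_window`` ps keeps single noisy tail samples
    from masquerading as persisting correlation.
    """
    values = series.values
    if len(series.times) > 1 and smooth_window > 0:
        dt = series.times[1] - series.times[0]
        w = max(1, int(round(smooth_window / dt)))
        if w > 1:
            values = np.convolve(values, np.ones(w) / w, mode="same")
    c = np.abs(values)
    above = np.flatnonzero(c >= threshold)
    if len(above) == 0:
        return 0.0
    if above[-1] + 1 >= len(c):
        raise ValueError("correlation never settles below the noise level "
                         "within the computed window")
    return float(series.times[above[-1] + 1])


def rdf_oo(trajectory: Trajectory, bin_width: float = 0.01, r_max: float = 1.0):
    """Oxygen-oxygen radial distribution of the water droplet.

    Density normalization uses the convex-hull volume of the oxygen
    positions per frame (the droplet is not periodic).  Returns
    (bin_centers, g_r).
    """
    structure = trajectory.structure
    osel = np.flatnonzero(structure.is_water & (structure.element == "O"))
    if len(osel) < 2:
        raise ValueError("need at least two water oxygens")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    shell_norm = 0.0
    n = len(osel)
    for f in range(trajectory.n_frames):
        pts = trajectory.coords[f][osel]
        try:
            hull = ConvexHull(pts)
        except Exception:                      # degenerate (coplanar) cloud
            hull = ConvexHull(pts, qhull_options="QJ")
        rho = n / hull.volume
        # edge correction: only atoms deeper than r_max inside the hull act
        # as reference centers, so every counted shell lies in the droplet
        depth = -(pts @ hull.equations[:, :3].T
                  + hull.equations[:, 3]).max(axis=1)
        ref = np.flatnonzero(depth >= r_max)
        if len(ref) == 0:
            ref = np.arange(n)                 # tiny cloud: no interior
        d = np.linalg.norm(pts[ref][:, None, :] - pts[None, :, :], axis=2)
        d = d[d > 1e-12]                       # drop self-distances
        hist += np.histogram(d, bins=edges)[0]
        shell_norm += len(ref) * rho
    centers = 0.5 * (edges[:-1] + edges[1:])
    shells = 4.0 * np.pi * centers ** 2 * bin_width
    g = hist / (shell_norm * shells)
    return centers, g


def rdf_extrema(centers: np.ndarray, g: np.ndarray, r_window=(0.2, 0.8)):
    """Positions of the first maximum and the first following local
    minimum of g(r) (a droplet g(r) also decays at large r, so a global
    minimum would land in the finite-size tail)."""
    mask = (centers >= r_window[0]) & (centers <= r_window[1])
    c, gg = centers[mask], g[mask]
    imax = int(np.argmax(gg))
    imin = None
    for i in range(imax + 1, len(gg) - 1):
        if gg[i] <= gg[i - 1] and gg[i] < gg[i + 1]:
            imin = i
            break
    if imin is None:
        imin = imax + int(np.argmin(gg[imax:]))
    return float(c[imax]), float(c[imin])


def pair_distances(trajectory: Trajectory, pairs) -> dict[str, TimeSeries]:
    """Per-frame distances for named atom pairs.

    ``pairs``: mapping label -> (i, j) atom indices, or a list of (i, j)
    tuples (labeled automatically).
    """
    if not isinstance(pairs, dict):
        pairs = {f"{i}-{j}": (i, j) for i, j in pairs}
    out = {}
    for label, (i, j) in pairs.items():
        i, j = int(i), int(j)
        if not (0 <= i < trajectory.structure.n_atoms
                and 0 <= j < trajectory.structure.n_atoms):
            raise ValueError(f"pair {label!r}: atom index out of range")
        d = np.linalg.norm(trajectory.coords[:, j] - trajectory.coords[:, i], axis=1)
        out[label] = TimeSeries(trajectory.times, d, label)
    return out
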