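"""Observables of the ensemble runs.

Radial distribution functions between body reference points (protein COM, NP
centre), first-peak extraction, aggregate detection by contact-graph
connectivity, and aggregate morphology from the gyration tensor (asphericity
and relative shape anisotropy κ², which separates linear clusters, κ²→1, from
globular ones, κ²→0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, sparse
from scipy.sparse.csgraph import connected_components


@dataclass
class RDFProfile:
    r: np.ndarray          # bin centres, Å
    g: np.ndarray          # dimensionless
    pair: str
    bin_width: float
    frames_used: int


def _min_image(d, box):
    if box is not None:
        d -= box * np.round(d / box)
    return d


def _pair_distance_histogram(a, b, same, box, edges):
    """Minimum-image pair distance histogram between point sets a and b."""
    d = a[:, None, :] - b[None, :, :]
    d = _min_image(d, box)
    r = np.linalg.norm(d, axis=2)
    if same:
        iu = np.triu_indices(len(a), k=1)
        r = r[iu]
    else:
        r = r.ravel()
    hist, _ = np.histogram(r, bins=edges)
    return hist


def compute_rdf(point_frames_a, point_frames_b, box, bin_width=1.0, r_max=None,
                pair="", same=None):
    """g(r) between two point selections over a trajectory.

    *point_frames_a/b* are lists of (n, 3) arrays (one per frame).  Pass the
    same list twice (or ``same=True``) for an A=A pair; self pairs are then
    excluded.  Normalization is against the ideal-gas shell count at the
    average densities in the periodic box.
    """
    box = np.asarray(box, dtype=float)
    if r_max is None:
        r_max = float(box.min()) / 2
    if r_max > box.min() / 2:
        raise ValueError("r_max must not exceed half the smallest box length")
    if same is None:
        same = point_frames_a is point_frames_b
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    centers = 0.5 * (edges[1:] + edges[:-1])
    hist = np.zeros(len(centers))
    volume = float(np.prod(box))
    norm_acc = 0.0
    nframes = len(point_frames_a)
    for fa, fb in zip(point_frames_a, point_frames_b):
        na, nb = len(fa), len(fb)
        hist += _pair_distance_histogram(fa, fb, same, box, edges)
        norm_acc += (na * (na - 1) / 2 if same else na * nb) / volume
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = shell * norm_acc
    g = np.divide(hist, ideal, out=np.zeros_like(hist), where=ideal > 0)
    return RDFProfile(r=centers, g=g, pair=pair, bin_width=bin_width,
                      frames_used=nframes)


def rdf_from_trajectory(traj, kind_a, kind_b, box, bin_width=1.0, r_max=None,
                        frame_slice=None):
    """Body-level g(r) (COM for proteins, centre bead for NPs)."""
    frames = range(traj.n_frames) if frame_slice is None else frame_slice
    pa = [traj.frame_points(t, kind_a) for t in frames]
    if kind_a == kind_b:
        return compute_rdf(pa, pa, box, bin_width, r_max,
                           pair=f"{kind_a}-{kind_b}", same=True)
    pb = [traj.frame_points(t, kind_b) for t in frames]
    return compute_rdf(pa, pb, box, bin_width, r_max,
                       pair=f"{kind_a}-{kind_b}", same=False)


def first_peak(rdf: RDFProfile, prominence_g=1.1):
    """Smallest-r local maximum with g above the prominence threshold.

    Returns (r, g) or None when no qualifying peak exists.
    """
    peaks, _ = signal.find_peaks(rdf.g, height=prominence_g)
    if len(peaks) == 0:
        return None
    k = peaks[0]
    return float(rdf.r[k]), float(rdf.g[k])


def refined_first_peak(rdf: RDFProfile, prominence_g=1.1):
    """First peak with parabolic sub-bin refinement; None when absent."""
    res = first_peak(rdf, prominence_g)
    if res is None:
        return None
    k = int(np.argmin(np.abs(rdf.r - res[0])))
    if k == 0 or k == len(rdf.r) - 1:
        return res
    y0, y1, y2 = rdf.g[k - 1], rdf.g[k], rdf.g[k + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return res
    shift = 0.5 * (y0 - y2) / denom
    return float(rdf.r[k] + shift * rdf.bin_width), float(y1)


# ---------------------------------------------------------------------------
# aggregates
# ---------------------------------------------------------------------------
def detect_aggregates(bead_coords, bead_body, box=None, cutoff=6.0):
    """Connected components of the body-contact graph.

    Two bodies are linked when any inter-body bead pair is closer than
    *cutoff* (minimum image).  Returns a list of sorted body-index lists,
    which partitions the bodies.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    bead_coords = np.asarray(bead_coords, dtype=float)
    bead_body = np.asarray(bead_body)
    from .forcefield import find_pairs
    if box is not None and np.any(np.asarray(box) < 2 * cutoff):
        # small test boxes: brute force instead of the tree
        d = bead_coords[:, None, :] - bead_coords[None, :, :]
        d = _min_image(d, np.asarray(box, dtype=float))
        r = np.linalg.norm(d, axis=2)
        i, j = np.where(np.triu(r < cutoff, k=1))
    else:
        i, j = find_pairs(bead_coords, cutoff, box)
    bi, bj = bead_body[i], bead_body[j]
    inter = bi != bj
    n = int(bead_body.max()) + 1 if len(bead_body) else 0
    graph = sparse.coo_matrix(
        (np.ones(inter.sum()), (bi[inter], bj[inter])), shape=(n, n))
    ncomp, labels = connected_components(graph, directed=False)
    clusters = [[] for _ in range(ncomp)]
    for body, lab in enumerate(labels):
        clusters[lab].append(body)
    return [sorted(c) for c in clusters]


def aggregate_shape(coms):
    """(asphericity, κ²) of a cluster from its member COM gyration tensor.

    asphericity = λ1 - (λ2 + λ3)/2 (λ1 largest);
    κ² = 1 - 3 (λ1λ2 + λ2λ3 + λ3λ1) / (λ1 + λ2 + λ3)².
    Returns None for clusters of fewer than two members.
    """
    coms = np.asarray(coms, dtype=float)
    if len(coms) < 2:
        return None
    d = coms - coms.mean(axis=0)
    gyr = d.T @ d / len(coms)
    lam = np.sort(np.linalg.eigvalsh(gyr))[::-1]
    asph = lam[0] - 0.5 * (lam[1] + lam[2])
    s1 = lam.sum()
    kappa2 = 1.0 - 3.0 * (lam[0] * lam[1] + lam[1] * lam[2] + lam[2] * lam[0]) / s1 ** 2
    return float(asph), float(min(max(kappa2, 0.0), 1.0))


def aggregate_report(traj, box, cutoff=6.0, frame_slice=None):
    """Per-frame clusters, size histogram and shape metrics for a trajectory."""
    frames = range(traj.n_frames) if frame_slice is None else frame_slice
    bead_body = np.concatenate(
        [np.full(b.n_beads, k) for k, b in enumerate(traj.bodies)])
    report = []
    for t in frames:
        coords = traj.frame_bead_coords(t)
        clusters = detect_aggregates(coords, bead_body, box, cutoff)
        shapes = []
        for members in clusters:
            # cluster COMs, unwrapped relative to the first member
            coms = np.array([traj.coms[t][m] for m in members])
            if box is not None:
                ref = coms[0]
                coms = ref + _min_image(coms - ref, np.asarray(box, dtype=float))
            shapes.append(aggregate_shape(coms))
        report.append({"time": traj.times[t], "clusters": clusters,
                       "shapes": shapes})
    return report


def write_rdf_tsv(rdf: RDFProfile, path):
    with open(path, "w") as fh:
        fh.write(f"# pair={rdf.pair} bin_width={rdf.bin_width} "
                 f"frames={rdf.frames_used}\nr_A\tg\n")
        for r, g in zip(rdf.r, rdf.g):
            fh.write(f"{r:.4f}\t{g:.6f}\n")
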