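"""Independent brute-force oracles used to cross-check the fast implementations.

Everything here is deliberately naive (nested loops, explicit 27-image
enumeration) and shares no code with the package's vectorized kernels.
"""

import itertools

import numpy as np


def brute_min_image_distance(p, q, box):
    """Minimum distance over all 27 explicit periodic images of q."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    box = np.asarray(box, dtype=float)
    best = np.inf
    for shift in itertools.product((-1, 0, 1), repeat=3):
        d = np.linalg.norm(p - (q + np.array(shift) * box))
        best = min(best, d)
    return best


def brute_min_distances(traj, ion_indices, protein_indices):
    """Per-ion, per-frame minimum distance via nested loops."""
    out = np.empty((len(ion_indices), traj.n_frames))
    for f, fr in enumerate(traj.frames):
        for a, i in enumerate(ion_indices):
            best = np.inf
            for j in protein_indices:
                best = min(best, brute_min_image_distance(fr.positions[i], fr.positions[j], fr.box))
            out[a, f] = best
    return out


def brute_retention(distances, cutoff):
    """Fraction of frames within cutoff, per ion (closed interval)."""
    return np.array([np.mean([d <= cutoff for d in row]) for row in distances])


def brute_residue_occupancy(traj, protein_indices, ion_indices, cutoff):
    """Per-residue contact occupancy via nested loops.

    Returns {(chain, resid): occupancy}.
    """
    topo = traj.topology
    res_keys = sorted(
        {(str(topo.chain_ids[j]), int(topo.residue_indices[j])) for j in protein_indices}
    )
    hits = {k: 0 for k in res_keys}
    for fr in traj.frames:
        touched = set()
        for j in protein_indices:
            key = (str(topo.chain_ids[j]), int(topo.residue_indices[j]))
            if key in touched:
                continue
            for i in ion_indices:
                d = brute_min_image_distance(fr.positions[j], fr.positions[i], fr.box)
                if d <= cutoff:
                    touched.add(key)
                    break
        for key in touched:
            hits[key] += 1
    return {k: hits[k] / traj.n_frames for k in res_keys}


def brute_cn_direct(traj, center_indices, water_indices, radius):
    """Mean count of waters within radius of each center, by explicit loops."""
    total = 0
    for fr in traj.frames:
        for i in center_indices:
            for j in water_indices:
                if brute_min_image_distance(fr.positions[i], fr.positions[j], fr.box) < radius:
                    total += 1
    return total / (traj.n_frames * len(center_indices))


def markov_retention_se(p_on, p_off, n_frames, n_ions):
    """Standard error of the mean realized bound fraction of the two-state chain.

    The per-frame indicator has variance pi(1-pi) and autocorrelation
    rho^|lag| with rho = 1 - p_on - p_off; the variance of its time average
    over n frames is (pi(1-pi)/n) * (1+rho)/(1-rho) for large n, and
    independent ions average down by n_ions.
    """
    pi = p_on / (p_on + p_off)
    rho = 1.0 - p_on - p_off
    var_mean = (pi * (1 - pi) / n_frames) * (1 + rho) / (1 - rho)
    return np.sqrt(var_mean / n_ions)
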