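"""Independent brute-force oracles used only by the test suite."""

import numpy as np


def quaternion_rmsd(mobile, reference):
    """Optimal-superposition RMSD via the Horn quaternion eigenvalue method.

    Fully independent of the SVD (Kabsch) route in the package.
    """
    p = np.asarray(mobile, dtype=float)
    q = np.asarray(reference, dtype=float)
    n = p.shape[0]
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    m = p.T @ q
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    msd = (np.sum(p ** 2) + np.sum(q ** 2) - 2.0 * lam) / n
    return float(np.sqrt(max(msd, 0.0)))


def brute_force_backbone_hbonds(atom_names, residue_numbers, coords,
                                distance_cutoff=3.5):
    """All-pairs N(i)...O(j) count with |i - j| >= 2, distance-only."""
    count = 0
    n = len(atom_names)
    for a in range(n):
        if atom_names[a] != "N":
            continue
        for b in range(n):
            if atom_names[b] != "O":
                continue
            if abs(int(residue_numbers[a]) - int(residue_numbers[b])) < 2:
                continue
            d = np.linalg.norm(np.asarray(coords[a]) - np.asarray(coords[b]))
            if d <= distance_cutoff:
                count += 1
    return count


def brute_force_rg(coords, weights):
    """Direct evaluation of the radius-of-gyration definition."""
    coords = np.asarray(coords, dtype=float)
    w = np.asarray(weights, dtype=float)
    com = (w[:, None] * coords).sum(axis=0) / w.sum()
    return float(np.sqrt((w * ((coords - com) ** 2).sum(axis=1)).sum() / w.sum()))
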