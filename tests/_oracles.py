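"""Independent brute-force oracles for the test suite.

Straight-line implementations of the information measures and of the
precision-recall / ROC sweeps, written with explicit loops and no code
shared with the package, so they can serve as an independent reference.
"""

import math

import numpy as np


def brute_information_measures(counts):
    """All measures for a 3-d joint frequency table (axes X, Y, Z; Z is the
    target), by direct evaluation of the defining formulas on the empirical
    distribution."""
    counts = np.asarray(counts, dtype=float)
    nx, ny, nz = counts.shape
    n = counts.sum()
    p = counts / n

    def log2(v):
        return math.log(v, 2)

    px = [sum(p[x, y, z] for y in range(ny) for z in range(nz)) for x in range(nx)]
    py = [sum(p[x, y, z] for x in range(nx) for z in range(nz)) for y in range(ny)]
    pz = [sum(p[x, y, z] for x in range(nx) for y in range(ny)) for z in range(nz)]
    pxy = [[sum(p[x, y, z] for z in range(nz)) for y in range(ny)] for x in range(nx)]
    pxz = [[sum(p[x, y, z] for y in range(ny)) for z in range(nz)] for x in range(nx)]
    pyz = [[sum(p[x, y, z] for x in range(nx)) for z in range(nz)] for y in range(ny)]

    def ent(dist):
        flat = np.asarray(dist, dtype=float).ravel()
        return -sum(q * log2(q) for q in flat if q > 0)

    h_x, h_y, h_z = ent(px), ent(py), ent(pz)
    h_xy, h_xz, h_yz = ent(pxy), ent(pxz), ent(pyz)
    h_xyz = ent(p)

    mi_xy = h_x + h_y - h_xy
    mi_xz = h_x + h_z - h_xz
    mi_yz = h_y + h_z - h_yz
    cmi_xy_z = h_xz + h_yz - h_xyz - h_z
    ii = cmi_xy_z - mi_xy

    # specific information of each z-state from each source
    def spec(p_st, p_s, z):
        # p_st: joint p(source, target) as nested list
        p_t = sum(p_st[s][z] for s in range(len(p_st)))
        total = 0.0
        for s in range(len(p_st)):
            if p_st[s][z] <= 0:
                continue
            p_s_given_z = p_st[s][z] / p_t
            p_z_given_s = p_st[s][z] / p_s[s]
            total += p_s_given_z * (log2(1.0 / p_t) - log2(1.0 / p_z_given_s))
        return total

    spec_x = [spec(pxz, px, z) for z in range(nz)]
    spec_y = [spec(pyz, py, z) for z in range(nz)]
    redundancy = sum(pz[z] * min(spec_x[z], spec_y[z]) for z in range(nz))
    unique_x = mi_xz - redundancy
    unique_y = mi_yz - redundancy
    synergy = ii + redundancy
    mi_joint = h_xy + h_z - h_xyz  # I({X,Y}; Z)

    return {
        "h_x": h_x, "h_y": h_y, "h_z": h_z,
        "mi_xy": mi_xy, "mi_xz": mi_xz, "mi_yz": mi_yz,
        "cmi_xy_z": cmi_xy_z, "ii": ii,
        "spec_x": spec_x, "spec_y": spec_y,
        "redundancy": redundancy, "unique_x": unique_x,
        "unique_y": unique_y, "synergy": synergy,
        "mi_joint": mi_joint,
    }


def brute_pr_roc(labels):
    """AUPR (step-wise interpolation) and AUROC (trapezoid) by recounting
    the confusion matrix at every prefix threshold of a 0/1 label order."""
    labels = [int(v) for v in labels]
    n = len(labels)
    n_pos = sum(labels)
    n_neg = n - n_pos
    aupr = 0.0
    prev_recall = 0.0
    roc_points = [(0.0, 0.0)]
    for k in range(1, n + 1):
        tp = sum(labels[:k])
        fp = k - tp
        precision = tp / k
        recall = tp / n_pos
        fpr = fp / n_neg
        if labels[k - 1] == 1:
            aupr += (recall - prev_recall) * precision
        prev_recall = recall
        roc_points.append((fpr, recall))
    auroc = 0.0
    for (x0, y0), (x1, y1) in zip(roc_points[:-1], roc_points[1:]):
        auroc += (x1 - x0) * (y0 + y1) / 2.0
    return aupr, auroc
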