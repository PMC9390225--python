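"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, BFS flood fill,
pairwise enumeration, hand ANOVA tables) and shares no code with the
package implementation it checks.
"""

from collections import deque

import numpy as np

_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
_OFFSETS_6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def flood_fill_components(selected: np.ndarray, connectivity: int = 26):
    """BFS connected components of a boolean grid; list of voxel-index sets."""
    offsets = _OFFSETS_26 if connectivity == 26 else _OFFSETS_6
    shape = selected.shape
    seen = np.zeros(shape, dtype=bool)
    comps = []
    for start in zip(*np.nonzero(selected)):
        if seen[start]:
            continue
        comp = set()
        q = deque([start])
        seen[start] = True
        while q:
            v = q.popleft()
            comp.add(v)
            for off in offsets:
                w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if any(c < 0 or c >= s for c, s in zip(w, shape)):
                    continue
                if selected[w] and not seen[w]:
                    seen[w] = True
                    q.append(w)
        comps.append(comp)
    return comps


def brute_hyper_volume_ml(hu, mask, spacing, hu_thr=30.0, min_ml=2.0,
                          pleura_label=2):
    """Total >threshold component volume within the pleura label (mL)."""
    vox = spacing[0] * spacing[1] * spacing[2]
    sel = (hu > hu_thr) & (mask == pleura_label)
    total = 0
    for comp in flood_fill_components(sel):
        if len(comp) * vox / 1000.0 >= min_ml:
            total += len(comp)
    return total * vox / 1000.0


def brute_gas_volume_ml(hu, mask, spacing, hu_thr=-850.0, min_ml=2.0,
                        pleura_label=2):
    """Total <threshold component volume within the pleura label (mL)."""
    vox = spacing[0] * spacing[1] * spacing[2]
    sel = (hu < hu_thr) & (mask == pleura_label)
    total = 0
    for comp in flood_fill_components(sel):
        if len(comp) * vox / 1000.0 >= min_ml:
            total += len(comp)
    return total * vox / 1000.0


def brute_pneumothorax_ml(hu, mask, body, spacing, hu_thr=-850.0, min_ml=2.0):
    """Naive pneumothorax rule: sub-threshold components outside
    lung/pleura/airway, inside the body, face-adjacent to lung or pleura,
    not sharing a sub-threshold component with airway voxels."""
    vox = spacing[0] * spacing[1] * spacing[2]
    sub = (hu < hu_thr) & body
    sub_comps = flood_fill_components(sub)
    comp_id = {}
    for i, comp in enumerate(sub_comps):
        for v in comp:
            comp_id[v] = i
    airway_ids = {comp_id[v] for v in zip(*np.nonzero(mask == 3)) if v in comp_id}
    candidate = sub & (mask != 1) & (mask != 2) & (mask != 3)
    total = 0.0
    for comp in flood_fill_components(candidate):
        if len(comp) * vox / 1000.0 < min_ml:
            continue
        adjacent = False
        for v in comp:
            for off in _OFFSETS_6:
                w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if any(c < 0 or c >= s for c, s in zip(w, hu.shape)):
                    continue
                if mask[w] in (1, 2):
                    adjacent = True
                    break
            if adjacent:
                break
        if not adjacent:
            continue
        if any(comp_id.get(v) in airway_ids for v in comp):
            continue
        total += len(comp) * vox / 1000.0
    return total


def pairwise_auc(scores, labels):
    """AUC as explicit concordance over all positive-negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    num = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                num += 1.0
            elif p == n:
                num += 0.5
    return num / (len(pos) * len(neg))


def anova_icc2(y):
    """ICC(2,1) from an explicitly assembled ANOVA table."""
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    gm = y.mean()
    msr = k * sum((y[i].mean() - gm) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((y[:, j].mean() - gm) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (y[i, j] - y[i].mean() - y[:, j].mean() + gm) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n), (msr, msc, mse)


def brute_ngtdm(levels_grid, region):
    """NGTDM features by explicit per-voxel neighbourhood enumeration.

    ``levels_grid`` holds 1-based grey levels (0 outside region).
    Returns a dict matching the package's key names.
    """
    shape = region.shape
    entries = []  # (level, |level - neighbourhood mean|)
    for v in zip(*np.nonzero(region)):
        nbrs = []
        for off in _OFFSETS_26:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if any(c < 0 or c >= s for c, s in zip(w, shape)):
                continue
            if region[w]:
                nbrs.append(levels_grid[w])
        if nbrs:
            entries.append((int(levels_grid[v]), abs(levels_grid[v] - np.mean(nbrs))))
    n_total = len(entries)
    ng = max(lv for lv, _ in entries)
    n_i = np.zeros(ng + 1)
    s_i = np.zeros(ng + 1)
    for lv, d in entries:
        n_i[lv] += 1
        s_i[lv] += d
    p_i = n_i / n_total
    present = [i for i in range(1, ng + 1) if p_i[i] > 0]
    ngp = len(present)
    ps = sum(p_i[i] * s_i[i] for i in present)
    s_sum = sum(s_i[i] for i in present)
    out = {
        "ngtdm_coarseness": min(1.0 / ps, 1e6) if ps > 0 else 1e6,
        "ngtdm_contrast": 0.0,
        "ngtdm_busyness": 0.0,
        "ngtdm_complexity": 0.0,
        "ngtdm_strength": 0.0,
    }
    if ngp > 1:
        out["ngtdm_contrast"] = (
            sum(
                p_i[i] * p_i[j] * (i - j) ** 2
                for i in present
                for j in present
            )
            / (ngp * (ngp - 1))
        ) * (s_sum / n_total)
        den = sum(
            abs(i * p_i[i] - j * p_i[j]) for i in present for j in present
        )
        out["ngtdm_busyness"] = ps / den if den > 0 else 0.0
        out["ngtdm_complexity"] = (
            sum(
                abs(i - j)
                * (p_i[i] * s_i[i] + p_i[j] * s_i[j])
                / (p_i[i] + p_i[j])
                for i in present
                for j in present
                if i != j
            )
            / n_total
        )
        if s_sum > 0:
            out["ngtdm_strength"] = (
                sum(
                    (p_i[i] + p_i[j]) * (i - j) ** 2
                    for i in present
                    for j in present
                )
                / s_sum
            )
    return out


def random_labelled_grid(rng, shape=(24, 24, 24), spacing=(1.0, 1.0, 1.0)):
    """A random blobby HU grid with lung/pleura/airway labels, for oracle
    equivalence checks. Smooth noise fields are thresholded so connected
    structures of nontrivial size appear."""
    from scipy import ndimage as ndi

    base = rng.normal(size=shape)
    smooth = ndi.gaussian_filter(base, sigma=2.0)
    mask = np.zeros(shape, dtype=np.uint8)
    mask[smooth > np.quantile(smooth, 0.55)] = 2  # pleura blob(s)
    lungfield = ndi.gaussian_filter(rng.normal(size=shape), sigma=2.0)
    lung_sel = (lungfield > np.quantile(lungfield, 0.7)) & (mask == 0)
    mask[lung_sel] = 1
    aw = np.zeros(shape, dtype=bool)
    aw[shape[0] // 2, shape[1] // 2, : shape[2] // 2] = True
    aw &= mask == 0
    mask[aw] = 3
    hu = np.full(shape, 40.0)
    hu[mask == 1] = -800.0
    hu[mask == 3] = -1000.0
    fluid = mask == 2
    hu[fluid] = 10.0
    blobfield = ndi.gaussian_filter(rng.normal(size=shape), sigma=1.5)
    hu[fluid & (blobfield > np.quantile(blobfield, 0.8))] = 60.0
    gasfield = ndi.gaussian_filter(rng.normal(size=shape), sigma=1.5)
    hu[fluid & (gasfield > np.quantile(gasfield, 0.9))] = -1000.0
    pocketfield = ndi.gaussian_filter(rng.normal(size=shape), sigma=2.0)
    pocket = (mask == 0) & (pocketfield > np.quantile(pocketfield, 0.85))
    hu[pocket] = -1000.0
    return hu, mask
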