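"""Brute-force reference implementations used as independent oracles.

Everything here is written in the most literal way possible (per-pixel
loops, stack-based flood fill, direct structuring-element scans) so the
tests compare the package's vectorized/library-backed operators against
unambiguous definitions.
"""

from __future__ import annotations

import numpy as np


def threshold_loop(image, red_min, red_green_margin, red_blue_margin):
    h, w, _ = image.shape
    out = np.zeros((h, w), dtype=np.uint8)
    for i in range(h):
        for j in range(w):
            r, g, b = (int(image[i, j, 0]), int(image[i, j, 1]), int(image[i, j, 2]))
            if r >= red_min and r - g >= red_green_margin and r - b >= red_blue_margin:
                out[i, j] = 1
    return out


def _neighbors(i, j, h, w, connectivity):
    if connectivity == 8:
        offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    for di, dj in offs:
        ni, nj = i + di, j + dj
        if 0 <= ni < h and 0 <= nj < w:
            yield ni, nj


def flood_fill_label(mask, connectivity=8):
    """Stack-based connected-component labeling; labels start at 1."""
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=np.int32)
    current = 0
    for i in range(h):
        for j in range(w):
            if mask[i, j] and labels[i, j] == 0:
                current += 1
                stack = [(i, j)]
                labels[i, j] = current
                while stack:
                    ci, cj = stack.pop()
                    for ni, nj in _neighbors(ci, cj, h, w, connectivity):
                        if mask[ni, nj] and labels[ni, nj] == 0:
                            labels[ni, nj] = current
                            stack.append((ni, nj))
    return labels, current


def remove_small_loop(mask, min_area, connectivity=8):
    labels, n = flood_fill_label(mask, connectivity)
    out = mask.copy()
    for lab in range(1, n + 1):
        area = int((labels == lab).sum())
        if area < min_area:
            out[labels == lab] = 0
    return out


def fill_holes_loop(mask, connectivity=8):
    """Flood background from the border; everything unreached becomes 1.

    Hole (background) connectivity is the complement of the foreground's.
    """
    bg_conn = 4 if connectivity == 8 else 8
    h, w = mask.shape
    reached = np.zeros((h, w), dtype=bool)
    stack = []
    for i in range(h):
        for j in (0, w - 1):
            if not mask[i, j] and not reached[i, j]:
                reached[i, j] = True
                stack.append((i, j))
    for j in range(w):
        for i in (0, h - 1):
            if not mask[i, j] and not reached[i, j]:
                reached[i, j] = True
                stack.append((i, j))
    while stack:
        ci, cj = stack.pop()
        for ni, nj in _neighbors(ci, cj, h, w, bg_conn):
            if not mask[ni, nj] and not reached[ni, nj]:
                reached[ni, nj] = True
                stack.append((ni, nj))
    out = mask.copy()
    out[~reached & (mask == 0)] = 1
    return out


def disk_offsets(radius):
    offs = []
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            if di * di + dj * dj <= radius * radius:
                offs.append((di, dj))
    return offs


def erode_loop(mask, radius):
    h, w = mask.shape
    offs = disk_offsets(radius)
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            ok = True
            for di, dj in offs:
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or not mask[ni, nj]:
                    ok = False
                    break
            out[i, j] = 1 if ok else 0
    return out


def dilate_loop(mask, radius):
    h, w = mask.shape
    offs = disk_offsets(radius)
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            if mask[i, j]:
                for di, dj in offs:
                    ni, nj = i + di, j + dj
                    if 0 <= ni < h and 0 <= nj < w:
                        out[ni, nj] = 1
    return out


def component_eccentricity(coords):
    """Eccentricity of the moment-equivalent ellipse of a pixel set."""
    ys = coords[:, 0].astype(float)
    xs = coords[:, 1].astype(float)
    ys -= ys.mean()
    xs -= xs.mean()
    # raw second-order central moments (each pixel treated as a point mass)
    myy = (ys * ys).mean()
    mxx = (xs * xs).mean()
    mxy = (xs * ys).mean()
    common = np.sqrt((mxx - myy) ** 2 + 4 * mxy**2)
    l1 = (mxx + myy + common) / 2.0
    l2 = (mxx + myy - common) / 2.0
    if l1 <= 0:
        return 0.0
    return float(np.sqrt(1.0 - l2 / l1))


def discard_stems_loop(mask, erosion_radius, dilation_radius, ecc_max,
                       connectivity=8):
    eroded = erode_loop(mask, erosion_radius)
    labels, n = flood_fill_label(eroded, connectivity)
    survivors = np.zeros_like(eroded)
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        if component_eccentricity(coords) <= ecc_max:
            survivors[labels == lab] = 1
    return dilate_loop(survivors, dilation_radius)


def confusion_loop(pred, gt):
    tp = tn = fp = fn = 0
    h, w = pred.shape
    for i in range(h):
        for j in range(w):
            if pred[i, j] and gt[i, j]:
                tp += 1
            elif pred[i, j] and not gt[i, j]:
                fp += 1
            elif not pred[i, j] and gt[i, j]:
                fn += 1
            else:
                tn += 1
    return tp, tn, fp, fn


def iou_sets(pred, gt, cls):
    """Set-based per-class IoU: |A n B| / |A u B| over pixels of class cls."""
    a = {(i, j) for i, j in np.argwhere(pred == cls)}
    b = {(i, j) for i, j in np.argwhere(gt == cls)}
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)
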