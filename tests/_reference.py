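"""Straight-line reference implementation of Mamdani inference.

Deliberately written without the package's vectorized code paths: pure
Python piecewise formulas, explicit loops, and Riemann integration.  It
serves as the independent oracle for the engine tests and must stay
structurally independent of ``fuzzyrehab.fuzzy``.
"""

from __future__ import annotations

import math


def ref_degree(shape: str, bps: tuple[float, ...], x: float) -> float:
    """Piecewise-linear membership degree, scalar, pure python."""
    if shape == "crisp_singleton":
        return 1.0 if x == bps[0] else 0.0
    if shape == "triangular":
        a, b, c = bps
        segs = [(a, 0.0), (b, 1.0), (c, 0.0)]
    else:
        a, b, c, d = bps
        segs = [(a, 0.0), (b, 1.0), (c, 1.0), (d, 0.0)]
    if x < segs[0][0] or x > segs[-1][0]:
        return 0.0
    # walk the vertices; vertical edges take the maximum of their endpoints
    best = 0.0
    for (x0, y0), (x1, y1) in zip(segs, segs[1:]):
        if x0 == x1:
            if x == x0:
                best = max(best, y0, y1)
        elif x0 <= x <= x1:
            best = max(best, y0 + (y1 - y0) * (x - x0) / (x1 - x0))
    return best


def ref_var_degree(var, label: str, x: float) -> float:
    for mf in var.labels:
        if mf.label == label:
            return ref_degree(mf.shape.value, mf.breakpoints, x)
    raise KeyError(label)


def ref_fuzzify(var, x: float) -> dict[str, float]:
    lo, hi = var.universe
    x = min(max(x, lo), hi)
    return {
        mf.label: ref_degree(mf.shape.value, mf.breakpoints, x)
        for mf in var.labels
    }


def ref_strengths(fis, inputs: dict[str, float]) -> list[float]:
    fuzz = {v.name: ref_fuzzify(v, inputs[v.name]) for v in fis.inputs}
    out = []
    for rule in fis.rules:
        s = 1.0
        for var, lab in rule.antecedents.items():
            if lab != "Any":
                s = min(s, fuzz[var][lab])
        out.append(s)
    return out


def ref_aggregate_at(fis, strengths, x: float) -> float:
    mu = 0.0
    for rule, s in zip(fis.rules, strengths):
        if s > 0.0:
            mu = max(mu, min(s, ref_var_degree(fis.output, rule.consequent, x)))
    return mu


def ref_centroid_riemann(fis, strengths, resolution: int) -> float | None:
    """Midpoint-Riemann centroid of the aggregate sampled at ``resolution``."""
    lo, hi = fis.output.universe
    n = resolution
    h = (hi - lo) / n
    num = den = 0.0
    for i in range(n):
        x = lo + (i + 0.5) * h
        mu = ref_aggregate_at(fis, strengths, x)
        num += x * mu
        den += mu
    if den <= 0.0:
        return None
    return num / den


def ref_centroid_of_polyline(xs, mus, factor: int = 10) -> float | None:
    """10x-resolution midpoint-Riemann centroid of a sampled aggregate.

    The sampled aggregate is treated as the piecewise-linear function it
    is; each grid cell is subdivided ``factor`` times.  Midpoint Riemann
    sums are exact on linear pieces, so this independently reproduces
    the exact centroid of the polyline.
    """
    num = den = 0.0
    for (x0, y0), (x1, y1) in zip(zip(xs, mus), zip(xs[1:], mus[1:])):
        h = (x1 - x0) / factor
        for j in range(factor):
            xm = x0 + (j + 0.5) * h
            ym = y0 + (y1 - y0) * (xm - x0) / (x1 - x0)
            num += xm * ym * h
            den += ym * h
    if den <= 0.0:
        return None
    return num / den


def ref_select_label(fis, value: float | None) -> str:
    if value is None:
        return fis.default_output_label
    order = fis.tie_break or tuple(mf.label for mf in fis.output.labels)
    rank = {name: i for i, name in enumerate(order)}
    best, best_key = None, None
    for mf in fis.output.labels:
        key = (ref_degree(mf.shape.value, mf.breakpoints, value), -rank[mf.label])
        if best_key is None or key > best_key:
            best, best_key = mf.label, key
    return best


def ref_infer_label(fis, inputs: dict[str, float], resolution: int = 20011) -> str:
    """End-to-end reference: fuzzify, fire, aggregate, dense centroid, label."""
    strengths = ref_strengths(fis, inputs)
    value = ref_centroid_riemann(fis, strengths, resolution)
    return ref_select_label(fis, value)
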