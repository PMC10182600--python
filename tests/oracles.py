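"""Brute-force O(n^2) reference implementations of the spatial metrics.

These deliberately avoid spatial indexing so that the package's accelerated
k-d tree paths can be checked against the literal definitions.
"""

import math

import numpy as np


def brute_mnnd(site, source, target, scheme=None):
    """Mean nearest-neighbor distance by exhaustive pairwise scan."""
    def leaves(label):
        return scheme.resolve(label) if scheme else {label}

    pheno = site.df["phenotype"]
    src = site.df.index[pheno.isin(leaves(source))]
    tgt = site.df.index[pheno.isin(leaves(target))]
    if len(src) == 0 or len(tgt) == 0:
        return math.nan, []
    xy = site.df[["x", "y"]].to_numpy(float)
    mins = []
    for a in src:
        best = math.inf
        for b in tgt:
            if b == a:
                continue
            dx = xy[a, 0] - xy[b, 0]
            dy = xy[a, 1] - xy[b, 1]
            d = math.sqrt(dx * dx + dy * dy)
            best = min(best, d)
        if math.isinf(best):
            return math.nan, []
        mins.append(best)
    return float(np.sum(mins)) / len(src), mins


def brute_ccps(site, phenotype, r=30.0, scheme=None, reference="cancer"):
    """Mean closed-ball neighbor count by exhaustive pairwise scan."""
    def leaves(label):
        return scheme.resolve(label) if scheme else {label}

    pheno = site.df["phenotype"]
    ref = site.df.index[pheno.isin(leaves(reference))]
    tgt = set(site.df.index[pheno.isin(leaves(phenotype))])
    if len(ref) == 0:
        return math.nan, []
    xy = site.df[["x", "y"]].to_numpy(float)
    counts = []
    for c in ref:
        k = 0
        for a in tgt:
            if a == c:
                continue
            if math.hypot(xy[c, 0] - xy[a, 0], xy[c, 1] - xy[a, 1]) <= r:
                k += 1
        counts.append(k)
    return float(np.sum(counts)) / len(ref), counts
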