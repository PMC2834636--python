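"""Mapping-function utilities, segregation tests and two-point grouping.

The Kosambi mapping function, x(r) = 25 ln((1+2r)/(1-2r)) cM, allows for
crossover interference and is the convention used for the maps this package
consumes and simulates.  Haldane's function, x(r) = -50 ln(1-2r), is
provided for comparison.  Segregation of full-sib (CP) markers is tested
against 1:1 (single-parent informative) or 1:2:1 (biparental, shared
alleles) with a chi-square test; distortion is flagged with the asterisk
scale used on the published maps and an exclusion flag at p < 1e-5.
Two-point linkage grouping estimates pairwise recombination fractions by
maximum likelihood over the CP transmission model and groups markers as
connected components at a LOD threshold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .maps import LinkageMap


class DomainError(ValueError):
    """Raised when a map-function argument is outside its domain."""


# ---------------------------------------------------------------------------
# mapping functions
# ---------------------------------------------------------------------------

def kosambi_cm(rf):
    """Kosambi map distance (cM) for recombination fraction ``rf`` in [0, 0.5)."""
    rf = np.asarray(rf, dtype=float)
    if np.any(rf < 0) or np.any(rf >= 0.5):
        raise DomainError("recombination fraction must be in [0, 0.5)")
    out = 25.0 * np.log((1 + 2 * rf) / (1 - 2 * rf))
    return float(out) if out.ndim == 0 else out


def kosambi_inverse(cm):
    """Recombination fraction for a Kosambi map distance (cM)."""
    cm = np.asarray(cm, dtype=float)
    if np.any(cm < 0):
        raise DomainError("map distance must be >= 0")
    out = 0.5 * np.tanh(cm / 50.0)
    return float(out) if out.ndim == 0 else out


def haldane_cm(rf):
    """Haldane map distance (cM) for recombination fraction ``rf`` in [0, 0.5)."""
    rf = np.asarray(rf, dtype=float)
    if np.any(rf < 0) or np.any(rf >= 0.5):
        raise DomainError("recombination fraction must be in [0, 0.5)")
    out = -50.0 * np.log(1 - 2 * rf)
    return float(out) if out.ndim == 0 else out


def haldane_inverse(cm):
    cm = np.asarray(cm, dtype=float)
    if np.any(cm < 0):
        raise DomainError("map distance must be >= 0")
    out = 0.5 * (1 - np.exp(-cm / 50.0))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# segregation distortion
# ---------------------------------------------------------------------------

#: significance thresholds of the map figures' asterisk scale, mildest first.
ASTERISK_THRESHOLDS = (0.1, 0.05, 0.01, 0.005, 0.001, 0.0005, 0.0001)
EXCLUSION_P = 1e-5

_EXPECTED_RATIOS = {
    "maternal_only": (1, 1),
    "paternal_only": (1, 1),
    "both": (1, 2, 1),
    "both_four_allele": (1, 1, 1, 1),
}


@dataclass
class SegregationResult:
    chi2: float
    df: int
    p: float
    flag: int          # number of asterisk thresholds crossed, 0-7
    excluded: bool     # p < 1e-5


def segregation_test(counts: Sequence[int],
                     informativeness: str = "maternal_only") -> SegregationResult:
    """Chi-square test of Mendelian segregation for one marker.

    ``counts`` are genotype-class counts: two classes for a single-parent
    informative marker (expected 1:1), three for a biparental shared-allele
    marker (expected 1:2:1), four for a fully informative four-allele
    configuration (expected 1:1:1:1).
    """
    if informativeness not in _EXPECTED_RATIOS:
        raise ValueError(f"unknown informativeness {informativeness!r}")
    ratio = _EXPECTED_RATIOS[informativeness]
    counts = np.asarray(counts, dtype=float)
    if counts.size != len(ratio):
        raise ValueError(
            f"{informativeness} expects {len(ratio)} genotype classes, "
            f"got {counts.size}")
    if (counts < 0).any():
        raise ValueError("negative counts")
    total = counts.sum()
    if total <= 0:
        raise ValueError("zero total count")
    expected = total * np.asarray(ratio, dtype=float) / sum(ratio)
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    df = counts.size - 1
    p = float(stats.chi2.sf(chi2, df))
    flag = int(sum(p < t for t in ASTERISK_THRESHOLDS))
    return SegregationResult(chi2=chi2, df=df, p=p, flag=flag,
                             excluded=p < EXCLUSION_P)


# ---------------------------------------------------------------------------
# two-point recombination and LOD grouping
# ---------------------------------------------------------------------------

_PARENT_GENOTYPES = {
    "lmxll": (("l", "m"), ("l", "l")),
    "nnxnp": (("n", "n"), ("n", "p")),
    "hkxhk": (("h", "k"), ("h", "k")),
}

MISSING = {"--", "", "NA", "nan"}


def _pair_class_probs(seg1: str, seg2: str, rf: float,
                      flip_m: int, flip_p: int) -> Dict[Tuple[str, str], float]:
    """Joint probability of observed genotype pairs under the CP model.

    Both meioses share recombination fraction ``rf``; ``flip_m``/``flip_p``
    encode the relative linkage phase of the two markers in each parent.
    """
    (m1, f1) = _PARENT_GENOTYPES[seg1]
    (m2, f2) = _PARENT_GENOTYPES[seg2]
    gam = {True: (1 - rf) / 2, False: rf / 2}
    probs: Dict[Tuple[str, str], float] = {}
    for hm1, hm2, hp1, hp2 in itertools.product((0, 1), repeat=4):
        p = gam[hm1 == hm2] * gam[hp1 == hp2]
        a1 = m1[hm1]
        a2 = m2[(hm2 + flip_m) % 2]
        b1 = f1[hp1]
        b2 = f2[(hp2 + flip_p) % 2]
        g = ("".join(sorted((a1, b1))), "".join(sorted((a2, b2))))
        probs[g] = probs.get(g, 0.0) + p
    return probs


def _pair_loglik(counts: Mapping[Tuple[str, str], int], seg1: str, seg2: str,
                 rf: float, flip_m: int, flip_p: int) -> float:
    probs = _pair_class_probs(seg1, seg2, rf, flip_m, flip_p)
    ll = 0.0
    for g, n in counts.items():
        p = probs.get(g, 0.0)
        if p <= 0:
            return -np.inf
        ll += n * np.log(p)
    return ll


@dataclass
class TwoPointResult:
    rf: float
    lod: float
    n: int


def two_point_rf(geno1: Sequence[str], geno2: Sequence[str],
                 seg1: str, seg2: str) -> TwoPointResult:
    """ML recombination fraction and LOD for one marker pair.

    Phase is unknown: the likelihood is maximized over the relative phase of
    each doubly heterozygous parent (equivalently, the phase minimizing the
    recombination fraction is chosen).  Pairs with no parent heterozygous at
    both markers carry no linkage information and return rf = 0.5, LOD = 0.
    """
    counts: Dict[Tuple[str, str], int] = {}
    for g1, g2 in zip(geno1, geno2):
        if str(g1) in MISSING or str(g2) in MISSING:
            continue
        key = (str(g1), str(g2))
        counts[key] = counts.get(key, 0) + 1
    n = sum(counts.values())
    mother_informative = (_PARENT_GENOTYPES[seg1][0][0] != _PARENT_GENOTYPES[seg1][0][1]
                          and _PARENT_GENOTYPES[seg2][0][0] != _PARENT_GENOTYPES[seg2][0][1])
    father_informative = (_PARENT_GENOTYPES[seg1][1][0] != _PARENT_GENOTYPES[seg1][1][1]
                          and _PARENT_GENOTYPES[seg2][1][0] != _PARENT_GENOTYPES[seg2][1][1])
    if n == 0 or not (mother_informative or father_informative):
        return TwoPointResult(rf=0.5, lod=0.0, n=n)

    flips_m = (0, 1) if mother_informative else (0,)
    flips_p = (0, 1) if father_informative else (0,)
    ll_null = _pair_loglik(counts, seg1, seg2, 0.5, 0, 0)
    best_ll, best_rf = -np.inf, 0.5
    for fm in flips_m:
        for fp in flips_p:
            res = optimize.minimize_scalar(
                lambda r: -_pair_loglik(counts, seg1, seg2, r, fm, fp),
                bounds=(1e-6, 0.5), method="bounded",
                options={"xatol": 1e-6})
            if -res.fun > best_ll:
                best_ll, best_rf = -res.fun, float(res.x)
    lod = max(0.0, (best_ll - ll_null) / np.log(10))
    return TwoPointResult(rf=best_rf, lod=lod, n=n)


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def two_point_grouping(genotypes: pd.DataFrame, seg_types: Mapping[str, str],
                       lod_threshold: float = 5.0) -> List[set]:
    """Group markers as connected components of the LOD graph.

    ``genotypes`` is offspring x marker; ``seg_types`` maps marker name to
    its CP segregation type (lmxll / nnxnp / hkxhk).  Edges connect pairs
    with LOD >= ``lod_threshold``; grouping is transitive by construction.
    Markers with no informative partner end up as singletons.
    """
    markers = [m for m in genotypes.columns if m in seg_types]
    if len(markers) < 2:
        raise ValueError("need at least two markers")
    uf = _UnionFind(markers)
    for i, m1 in enumerate(markers):
        for m2 in markers[i + 1:]:
            res = two_point_rf(genotypes[m1], genotypes[m2],
                               seg_types[m1], seg_types[m2])
            if res.lod >= lod_threshold:
                uf.union(m1, m2)
    comps: Dict[str, set] = {}
    for m in markers:
        comps.setdefault(uf.find(m), set()).add(m)
    return sorted(comps.values(), key=lambda s: sorted(s)[0])


# ---------------------------------------------------------------------------
# map summaries
# ---------------------------------------------------------------------------

def mean_marker_interval(total_cm: float, n_markers: int) -> float:
    """Mean interval = total map length / marker count.

    Division is by the marker count, not the interval count: this is the
    convention that reproduces the published values for both maps
    (2477/495 = 5.0 cM and 1793/221 = 8.1 cM).
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    return total_cm / n_markers


def map_summary(lmap: LinkageMap) -> dict:
    """Marker count, total length (sum of group spans) and mean interval."""
    n = lmap.n_markers
    if n == 0:
        raise ValueError("empty map")
    total = lmap.total_cm
    return {
        "n_markers": n,
        "n_groups": len(lmap.groups),
        "total_cm": total,
        "mean_interval_cm": mean_marker_interval(total, n),
    }
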