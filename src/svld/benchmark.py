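"""Benchmark a merged call set against a reference SV set.

Matching re-implements the Truvari bench predicate (refdist / pctsize /
pctovl) rather than shelling out, so it is hermetically testable:
two SVs match when they share a type, their start- or end-breakpoints lie
within ``refdist`` bp, their lengths agree within ``pctsize``, and (for
non-insertions) they reciprocally overlap by at least ``pctovl``.
Sequence similarity (Truvari's pctseq) is not compared because consensus
calls carry no ALT sequences.  ``refdist`` is applied to the minimum of
the start-distance and the end-distance, an approximation of Truvari's
reference-context semantics.

Agreement of non-reference allele frequencies between matched call sets
is summarized with Lin's concordance correlation coefficient (CCC), with
a 95% confidence interval from the Fisher z-transform per Lin (1989).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import genotype_class
from .sv_merge import reciprocal_overlap

UNDEFINED = float("nan")


@dataclass
class MatchConfig:
    refdist: int = 500
    pctsize: float = 0.7
    pctovl: float = 0.5

    def __post_init__(self) -> None:
        if self.refdist < 0:
            raise ValueError("refdist must be >= 0")
        for frac in (self.pctsize, self.pctovl):
            if not (0 < frac <= 1):
                raise ValueError("pctsize/pctovl must lie in (0, 1]")


@dataclass
class ConcordanceResult:
    n_base: int
    n_comp: int
    matches: list[tuple[int, int]]  # (base index, comp index)
    recall: float
    precision: float
    recall_by_naf: dict[float, float] = field(default_factory=dict)
    genotype_concordance: float = UNDEFINED
    ccc: float = UNDEFINED
    ccc_ci: tuple[float, float] = (UNDEFINED, UNDEFINED)


def sv_pair_match(a, b, cfg: MatchConfig) -> bool:
    """Truvari-parameterized match between a call and a reference SV."""
    if a.svtype != b.svtype or a.chrom != b.chrom:
        return False
    if min(abs(a.start - b.start), abs(a.end - b.end)) > cfg.refdist:
        return False
    lo, hi = sorted((a.length, b.length))
    if hi == 0 or lo / hi < cfg.pctsize:
        return False
    if a.svtype != "INS":
        if reciprocal_overlap((a.start, a.end), (b.start, b.end)) < cfg.pctovl:
            return False
    return True


def _breakpoint_distance(a, b) -> tuple[int, int]:
    return (min(abs(a.start - b.start), abs(a.end - b.end)), abs(a.start - b.start))


def match_sets(base: list, comp: list, cfg: MatchConfig | None = None) -> ConcordanceResult:
    """Greedy one-to-one matching of a call set against a base set.

    Base calls are visited in sorted genomic order; each takes the
    unmatched comparison call with the smallest breakpoint distance among
    those passing the match predicate.  recall = matches / n_base,
    precision = matches / n_comp.
    """
    cfg = cfg or MatchConfig()
    base_order = sorted(
        range(len(base)), key=lambda i: (base[i].chrom, base[i].start, base[i].end)
    )
    comp_order = sorted(
        range(len(comp)), key=lambda j: (comp[j].chrom, comp[j].start, comp[j].end)
    )
    used: set[int] = set()
    matches: list[tuple[int, int]] = []
    for i in base_order:
        best_j = None
        best_key = None
        for j in comp_order:
            if j in used or not sv_pair_match(base[i], comp[j], cfg):
                continue
            key = _breakpoint_distance(base[i], comp[j])
            if best_key is None or key < best_key:
                best_j, best_key = j, key
        if best_j is not None:
            used.add(best_j)
            matches.append((i, best_j))
    matches.sort()
    recall = len(matches) / len(base) if base else UNDEFINED
    precision = len(matches) / len(comp) if comp else UNDEFINED
    return ConcordanceResult(
        n_base=len(base),
        n_comp=len(comp),
        matches=matches,
        recall=recall,
        precision=precision,
    )


def recall_by_naf(
    result: ConcordanceResult,
    base_nafs: list[float],
    thresholds: tuple[float, ...] = (0.1, 0.5),
) -> dict[float, float]:
    """Recall restricted to base SVs with NAF strictly above each threshold.

    An empty stratum yields NaN (undefined), never zero.
    """
    if len(base_nafs) != result.n_base:
        raise ValueError("one NAF per base SV is required")
    matched_base = {i for i, _ in result.matches}
    out: dict[float, float] = {}
    for t in thresholds:
        stratum = [i for i, naf in enumerate(base_nafs) if naf > t]
        if not stratum:
            out[t] = UNDEFINED
            continue
        out[t] = sum(1 for i in stratum if i in matched_base) / len(stratum)
    result.recall_by_naf.update(out)
    return out


def genotype_concordance(
    matches: list[tuple[int, int]],
    base_gts: list[str],
    comp_gts: list[str],
) -> float:
    """Fraction of matched pairs with the same unphased genotype class.

    Pairs with a missing genotype on either side are excluded from the
    denominator; an empty denominator yields NaN.
    """
    n_used = n_same = 0
    for i, j in matches:
        gb, gc = genotype_class(base_gts[i]), genotype_class(comp_gts[j])
        if gb == "./." or gc == "./.":
            continue
        n_used += 1
        n_same += gb == gc
    return n_same / n_used if n_used else UNDEFINED


def lin_ccc(x, y, alpha: float = 0.05) -> tuple[float, float, float]:
    """Lin's concordance correlation coefficient with its CI.

    ccc = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2), with 1/n moment
    estimators per Lin's original definition.  The (1 - alpha) CI comes
    from the Fisher z-transform with Lin's (1989) standard error.
    Degenerate inputs (|ccc| = 1 or zero Pearson correlation) return a
    point interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("lin_ccc requires paired vectors of length >= 3")
    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise ValueError("lin_ccc undefined: zero total variance")
    ccc = 2 * sxy / denom

    if sx2 == 0 or sy2 == 0:
        return ccc, ccc, ccc
    r = sxy / math.sqrt(sx2 * sy2)
    if abs(ccc) >= 1 or r == 0:
        return ccc, ccc, ccc
    u = (mx - my) / (sx2 * sy2) ** 0.25
    one_m = 1 - ccc**2
    se_z2 = (
        (1 - r**2) * ccc**2 / (one_m * r**2)
        + 4 * ccc**3 * (1 - ccc) * u**2 / (r * one_m**2)
        - 2 * ccc**4 * u**4 / (r**2 * one_m**2)
    ) / (n - 2)
    se_z = math.sqrt(max(se_z2, 0.0))
    z = math.atanh(ccc)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    lo = math.tanh(z - zcrit * se_z)
    hi = math.tanh(z + zcrit * se_z)
    return ccc, lo, hi


def benchmark_sets(
    base: list,
    comp: list,
    cfg: MatchConfig | None = None,
    base_nafs: list[float] | None = None,
    comp_nafs: list[float] | None = None,
    base_gts: list[str] | None = None,
    comp_gts: list[str] | None = None,
    naf_thresholds: tuple[float, ...] = (0.1, 0.5),
) -> ConcordanceResult:
    """Full benchmark: matching, NAF-stratified recall, genotype
    concordance and the NAF concordance correlation coefficient."""
    result = match_sets(base, comp, cfg)
    if base_nafs is not None:
        recall_by_naf(result, base_nafs, naf_thresholds)
    if base_gts is not None and comp_gts is not None:
        result.genotype_concordance = genotype_concordance(
            result.matches, base_gts, comp_gts
        )
    if base_nafs is not None and comp_nafs is not None and len(result.matches) >= 3:
        xs = [base_nafs[i] for i, _ in result.matches]
        ys = [comp_nafs[j] for _, j in result.matches]
        try:
            ccc, lo, hi = lin_ccc(xs, ys)
            result.ccc, result.ccc_ci = ccc, (lo, hi)
        except ValueError:
            pass
    return result
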