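"""Maximum-likelihood heteroplasmy calling.

Mitochondrial variant calling resembles somatic calling: any allele
frequency in [0, 1] is possible and several alleles can segregate at one
site.  At each site the variant allele fractions (VAFs) of all candidate
alleles are estimated jointly by maximising

    L(f) = sum_{i,j} c_{i,j} ln p(f_i, e_j),     p(f, e) = f(1-e) + (1-f)e

where ``c_{i,j}`` counts observations of allele ``i`` at quality level
``j`` and ``e_j`` is the Phred error probability of level ``j``.  The
frequencies sum to one, so with ``m`` alleles there are ``m - 1`` free
parameters and the baseline frequency is ``f_0 = 1 - sum_{i>0} f_i``.
Maximisation uses Fisher scoring (Newton steps with the expected
information matrix), with backtracking to keep the likelihood
non-decreasing and all frequencies non-negative; alleles driven to the
zero boundary with a negative partial derivative are removed.  Standard
errors come from the inverse information matrix and each retained allele
gets a likelihood-ratio test of VAF > 0.

Long deletions are handled separately: runs of consecutive sites with a
retained deletion allele are located, the per-read deletion intervals in
each run are clustered by breakpoints, each cluster is re-estimated as an
allele against the spanning reads, and single-site estimates inside the
run are recomputed without the deletion-carrying reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .model import MitoGenome, QualityModel, obs_likelihood
from .pileup import (
    CHAR_OF,
    DEL,
    DEL_ALLELE,
    Pileup,
    ReadDeletionInterval,
    SKIP,
    SiteCounts,
    encode_seq,
)

QUAL_CAP = 10_000.0


@dataclass
class CallerThresholds:
    """Filtering and numerical parameters of the caller.

    The statistical filters are conservative defaults: ``p_strand`` and
    ``p_qual`` bound the Fisher strand-bias and Mann-Whitney base-quality
    tests, ``qual_min_call`` the phred-scaled LRT quality, and
    ``low_freq_threshold`` marks calls below 0.5% VAF as low frequency
    rather than dropping them.
    """

    p_strand: float = 1e-3
    p_qual: float = 1e-3
    qual_min_call: float = 30.0
    low_freq_threshold: float = 0.005
    long_del_min: int = 64
    merge_tol: int = 10
    max_window: int = 50
    tol: float = 1e-8
    max_iter: int = 100


@dataclass
class FrequencyEstimate:
    allele: str
    f_hat: float
    se: float
    lr_stat: float = 0.0
    qual: float = 0.0


@dataclass
class FitResult:
    """Joint VAF fit at one site; allele 0 is the baseline."""

    alleles: list[str]
    f_hat: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int


@dataclass
class VariantCall:
    position: int  # 0-based
    ref: str
    alts: list[str]
    estimates: list[FrequencyEstimate]
    depth_fwd: dict[str, int]
    depth_rev: dict[str, int]
    filters: list[str] = field(default_factory=list)
    baseline: str = ""

    @property
    def filter_field(self) -> str:
        return ";".join(self.filters) if self.filters else "PASS"


@dataclass
class DeletionAllele:
    """A long deletion with clustered breakpoints (0-based start)."""

    start: int
    length: int
    n_reads: int
    f_hat: float
    se: float

    @property
    def end(self) -> int:
        """1-based last deleted position (``m.{start+1}_{end}del``)."""
        return self.start + self.length

    def name(self) -> str:
        return f"m.{self.start + 1}_{self.end}del"


@dataclass
class MergedCall:
    """A multi-site haplotype call over a short indel window."""

    start: int  # 0-based anchor
    ref: str
    haplotypes: list[str]  # view strings, '-' marks deleted bases
    estimates: list[FrequencyEstimate]
    filters: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Fisher-scoring VAF estimation
# ---------------------------------------------------------------------------


def _loglik(f: np.ndarray, counts: np.ndarray, errors: np.ndarray) -> float:
    p = np.outer(f, 1.0 - 2.0 * errors) + errors
    return float((counts * np.log(p)).sum())


def _score(f, counts, errors, free):
    """Partial derivatives of L for the free alleles (index > 0)."""
    p = np.outer(f, 1.0 - 2.0 * errors) + errors
    w = 1.0 - 2.0 * errors
    base = counts[0] / p[0]
    return np.array([(w * (counts[i] / p[i] - base)).sum() for i in free])


def _information(f, counts, errors, free):
    """Expected information matrix over the free alleles."""
    p = np.outer(f, 1.0 - 2.0 * errors) + errors
    w2 = (1.0 - 2.0 * errors) ** 2
    c_j = counts.sum(axis=0)
    off = (w2 * c_j / p[0]).sum()
    k = len(free)
    info = np.full((k, k), off)
    for a, i in enumerate(free):
        info[a, a] = (w2 * c_j * (1.0 / p[i] + 1.0 / p[0])).sum()
    return info


def fit_frequencies(
    counts: np.ndarray,
    errors: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    fixed_zero: Sequence[int] = (),
) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    """Maximise L(f) by Fisher scoring.

    Parameters
    ----------
    counts:
        ``(m, J)`` observation counts; allele 0 is the baseline whose
        frequency is ``1 - sum`` of the others.
    errors:
        ``(J,)`` error probabilities per quality level, each in (0, 0.5).
    fixed_zero:
        allele indices (> 0) constrained to frequency 0 (used for the
        likelihood-ratio tests).

    Returns ``(f_hat, se, loglik, converged, n_iter)``.
    """
    m, J = counts.shape
    if errors.shape != (J,):
        raise ValueError("errors must have one entry per quality level")
    if np.any((errors <= 0) | (errors >= 0.5)):
        raise ValueError("error probabilities must lie in (0, 0.5)")

    total = counts.sum()
    f = counts.sum(axis=1) / total if total > 0 else np.full(m, 1.0 / m)
    f = f.astype(float)
    free = [i for i in range(1, m) if i not in set(fixed_zero)]
    for i in fixed_zero:
        f[i] = 0.0
    f[0] = max(1.0 - f[1:].sum(), 0.0)

    ll = _loglik(f, counts, errors)
    converged = False
    it = 0
    while free and it < max_iter:
        it += 1
        S = _score(f, counts, errors, free)
        # an allele pinned at 0 with a negative partial derivative has its
        # maximum-likelihood estimate below 0: fix it at zero and drop it
        at_zero_neg = [i for a, i in enumerate(free) if f[i] == 0.0 and S[a] < 0]
        if at_zero_neg:
            for i in at_zero_neg:
                free.remove(i)
            continue
        info = _information(f, counts, errors, free)
        try:
            delta = np.linalg.solve(info, S)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(info, S, rcond=None)[0]
        if f[0] <= 1e-12 and delta.sum() > 0:
            # the baseline sits at its zero boundary and the unconstrained
            # step would push it negative: take the equality-constrained
            # Newton step instead (mass only moves between free alleles)
            k = len(free)
            kkt = np.zeros((k + 1, k + 1))
            kkt[:k, :k] = info
            kkt[:k, k] = 1.0
            kkt[k, :k] = 1.0
            rhs = np.zeros(k + 1)
            rhs[:k] = S
            try:
                delta = np.linalg.solve(kkt, rhs)[:k]
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(kkt, rhs, rcond=None)[0][:k]
        # project the step so zero-frequency alleles are not pushed negative
        for a, i in enumerate(free):
            if f[i] == 0.0 and delta[a] < 0:
                delta[a] = 0.0
        if not np.any(delta):
            converged = True
            break

        # largest step keeping every frequency (incl. the baseline) >= 0
        t_max = 1.0
        for a, i in enumerate(free):
            if delta[a] < 0:
                t_max = min(t_max, f[i] / -delta[a])
        dsum = delta.sum()
        if dsum > 1e-12:
            t_max = min(t_max, f[0] / dsum)

        new_f, new_ll, accepted = None, None, False
        a_step = 1.0
        for _ in range(60):
            t = min(a_step, t_max)
            if t <= 0.0:
                break
            cand = f.copy()
            for a, i in enumerate(free):
                cand[i] = max(f[i] + t * delta[a], 0.0)
            cand[0] = max(1.0 - cand[1:].sum(), 0.0)
            cand_ll = _loglik(cand, counts, errors)
            if cand_ll >= ll - 1e-12:
                new_f, new_ll, accepted = cand, cand_ll, True
                break
            a_step /= 2.0
        if not accepted:
            converged = True  # no a > 0 increases the likelihood
            break

        hit_zero = [i for i in free if new_f[i] <= 1e-12]
        f, prev_ll, ll = new_f, ll, new_ll
        for i in hit_zero:
            f[i] = 0.0
        if hit_zero:
            S2 = _score(f, counts, errors, free)
            for i in hit_zero:
                if S2[free.index(i)] < 0:
                    free.remove(i)
        if abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1.0):
            converged = True
            break

    se = np.zeros(m)
    if free:
        info = _information(f, counts, errors, free)
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
        diag = np.clip(np.diag(cov), 0.0, None)
        for a, i in enumerate(free):
            se[i] = math.sqrt(diag[a])
        se[0] = math.sqrt(max(float(cov.sum()), 0.0))
    return f, se, ll, converged or not free, it


# ---------------------------------------------------------------------------
# Site-level calling
# ---------------------------------------------------------------------------


def candidate_alleles(site: SiteCounts, ref_allele: str) -> list[str]:
    """Alleles with at least 2 observations on each strand.

    The reference allele is always retained as the baseline, whether or
    not it passes the per-strand rule.
    """
    retained = []
    for allele in site.alleles():
        fwd, rev = site.strand_counts(allele)
        if fwd >= 2 and rev >= 2:
            retained.append(allele)
    if ref_allele not in retained:
        retained.insert(0, ref_allele)
    return retained


def _count_matrix(
    site: SiteCounts, alleles: list[str], qm: QualityModel
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    levels = sorted({q for (_a, _s, q) in site.counts})
    if not levels:
        levels = [qm.q_min]
    counts = np.zeros((len(alleles), len(levels)), dtype=float)
    level_ix = {q: j for j, q in enumerate(levels)}
    for (a, _s, q), n in site.counts.items():
        if a in alleles:
            counts[alleles.index(a), level_ix[q]] += n
    errors = np.array([qm.error_prob(q) for q in levels])
    return counts, errors, levels


def phred_from_lrt(lr_stat: float) -> float:
    """Phred-scaled quality of a chi-square(1) likelihood-ratio statistic."""
    if lr_stat <= 0:
        return 0.0
    p = stats.chi2.sf(lr_stat, df=1)
    if p <= 0:
        return QUAL_CAP
    return min(-10.0 * math.log10(p), QUAL_CAP)


def estimate_vaf(
    site: SiteCounts,
    qm: QualityModel,
    ref_allele: str,
    thresholds: CallerThresholds | None = None,
) -> FitResult:
    """Joint VAF estimate at one site, with SEs and per-allele LRTs.

    The baseline allele is the reference (or, when the reference is
    entirely unobserved, the most frequent allele).  The returned
    ``FitResult`` lists the baseline first.
    """
    th = thresholds or CallerThresholds()
    retained = candidate_alleles(site, ref_allele)
    baseline = ref_allele
    totals = {a: sum(site.by_quality(a).values()) for a in retained}
    if totals.get(baseline, 0) == 0 and len(retained) > 1:
        baseline = max(totals, key=lambda a: totals[a])
    alleles = [baseline] + [a for a in retained if a != baseline]
    counts, errors, _ = _count_matrix(site, alleles, qm)
    f, se, ll, conv, it = fit_frequencies(
        counts, errors, tol=th.tol, max_iter=th.max_iter
    )
    return FitResult(alleles, f, se, ll, conv, it)


def lrt_qualities(
    fit: FitResult, site: SiteCounts, qm: QualityModel, th: CallerThresholds
) -> list[FrequencyEstimate]:
    """Per-allele LRT for VAF > 0, on the alleles retained by the fit."""
    counts, errors, _ = _count_matrix(site, fit.alleles, qm)
    out = []
    for i, allele in enumerate(fit.alleles):
        if i == 0:
            out.append(FrequencyEstimate(allele, float(fit.f_hat[0]), float(fit.se[0])))
            continue
        est = FrequencyEstimate(allele, float(fit.f_hat[i]), float(fit.se[i]))
        if fit.f_hat[i] > 0:
            _f0, _se0, ll0, _c, _n = fit_frequencies(
                counts, errors, tol=th.tol, max_iter=th.max_iter, fixed_zero=[i]
            )
            est.lr_stat = max(2.0 * (fit.loglik - ll0), 0.0)
            est.qual = phred_from_lrt(est.lr_stat)
        out.append(est)
    return out


# ---------------------------------------------------------------------------
# Long deletions
# ---------------------------------------------------------------------------


def _deletion_runs(del_retained: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal circular runs of True of length >= min_len, as (start, length)."""
    l = len(del_retained)
    if del_retained.all():
        return [(0, l)]
    runs = []
    x = np.asarray(del_retained, dtype=bool)
    # rotate so position 0 is False, making every run linear
    first_false = int(np.argmin(x))
    rot = np.roll(x, -first_false)
    diff = np.diff(rot.astype(np.int8))
    starts = np.nonzero(diff == 1)[0] + 1
    ends = np.nonzero(diff == -1)[0] + 1
    for s in starts:
        e = ends[ends > s]
        e = int(e[0]) if len(e) else l
        if e - s >= min_len:
            runs.append(((s + first_false) % l, e - s))
    return runs


def _cluster_deletions(
    dels: list[ReadDeletionInterval], merge_tol: int
) -> list[list[ReadDeletionInterval]]:
    """Greedy clustering by breakpoint similarity (start and length)."""
    clusters: list[list[ReadDeletionInterval]] = []
    for rd in sorted(dels, key=lambda r: (r.start, r.length)):
        placed = False
        for cl in clusters:
            s = int(np.median([c.start for c in cl]))
            ln = int(np.median([c.length for c in cl]))
            if abs(rd.start - s) <= merge_tol and abs(rd.length - ln) <= merge_tol:
                cl.append(rd)
                placed = True
                break
        if not placed:
            clusters.append([rd])
    return clusters


def detect_long_deletions(
    pile: Pileup,
    qm: QualityModel,
    thresholds: CallerThresholds | None = None,
) -> tuple[list[DeletionAllele], dict[int, set[int]], list[tuple[int, int]]]:
    """Find, cluster and quantify long deletions.

    Returns the deletion alleles, a map ``region start -> rows to exclude``
    (the reads carrying a clustered deletion, to be ignored when
    re-estimating single-site frequencies inside the region), and the
    regions themselves as ``(start, length)``.
    """
    th = thresholds or CallerThresholds()
    counts = pile.code_counts(qm)
    del_retained = (counts[DEL, 0] >= 2) & (counts[DEL, 1] >= 2)
    regions = _deletion_runs(del_retained, th.long_del_min)
    alleles: list[DeletionAllele] = []
    exclusions: dict[int, set[int]] = {}
    for start, length in regions:
        in_region = [
            rd
            for rd in pile.deletions
            if rd.length >= th.long_del_min
            and (rd.start - start) % pile.l < length
        ]
        if not in_region:
            continue
        clusters = _cluster_deletions(in_region, th.merge_tol)
        carrier_rows = {rd.row for cl in clusters for rd in cl}
        exclusions[start] = carrier_rows

        # frequency estimation: deletion clusters vs intact spanning reads.
        # every read covering the anchor base just before the region spans it
        anchor = (start - 1) % pile.l
        spanning = set(int(r) for r in np.nonzero(pile.codes[:, anchor] != SKIP)[0])
        spanning |= carrier_rows
        cluster_of: dict[int, int] = {}
        for ci, cl in enumerate(clusters):
            for rd in cl:
                cluster_of[rd.row] = ci
        site = SiteCounts(start)
        for row in spanning:
            ci = cluster_of.get(row)
            if ci is None:
                q = int(pile.quals[row, anchor])
                if q < qm.q_min:
                    continue
                site.add("ref", pile.strands[row], q)
            else:
                rd = next(r for r in clusters[ci] if r.row == row)
                site.add(f"del{ci}", pile.strands[row], max(rd.qual, qm.q_min))
        names = ["ref"] + [f"del{ci}" for ci in range(len(clusters))]
        names = [n for n in names if any(a == n for (a, _s, _q) in site.counts)]
        cmat, errs, _ = _count_matrix(site, names, qm)
        f, se, _ll, _conv, _it = fit_frequencies(cmat, errs, tol=th.tol, max_iter=th.max_iter)
        for ci, cl in enumerate(clusters):
            name = f"del{ci}"
            if name not in names:
                continue
            i = names.index(name)
            alleles.append(
                DeletionAllele(
                    start=int(np.median([r.start for r in cl])),
                    length=int(np.median([r.length for r in cl])),
                    n_reads=len(cl),
                    f_hat=float(f[i]),
                    se=float(se[i]),
                )
            )
    alleles.sort(key=lambda a: (a.start, a.length))
    return alleles, exclusions, regions


# ---------------------------------------------------------------------------
# Short indel haplotype merging
# ---------------------------------------------------------------------------


def merge_indel_haplotypes(
    pile: Pileup,
    genome: MitoGenome,
    qm: QualityModel,
    thresholds: CallerThresholds | None = None,
    exclude_rows: set[int] | None = None,
) -> list[MergedCall]:
    """Merge short deletion runs with their anchor site into haplotype calls.

    Each run of consecutive sites with a retained (short) deletion allele,
    preceded by an anchor site without one, is merged left to right: the
    candidate merged alleles are the product of the per-site retained
    alleles, their counts are taken from the reads spanning the window,
    and the VAF fit is re-run on the merged counts, pruning alleles
    estimated at zero after each extension.
    """
    th = thresholds or CallerThresholds()
    excl = exclude_rows or set()
    keep = np.array([r not in excl for r in range(pile.n_reads)], dtype=bool)
    codes = pile.codes[keep]
    quals = pile.quals[keep]
    strands = [s for r, s in enumerate(pile.strands) if r not in excl]

    ok = (codes != SKIP) & (quals >= qm.q_min)
    fwd = np.array([s == "+" for s in strands], dtype=bool)[:, None]
    del_f = ((codes == DEL) & ok & fwd).sum(axis=0)
    del_r = ((codes == DEL) & ok & ~fwd).sum(axis=0)
    retained_del = (del_f >= 2) & (del_r >= 2)

    calls: list[MergedCall] = []
    l = pile.l
    pos = 0
    while pos < l:
        if not retained_del[pos]:
            pos += 1
            continue
        run_start = pos
        while pos < l and retained_del[pos]:
            pos += 1
        run_len = pos - run_start
        if run_len >= th.long_del_min or run_start == 0:
            continue  # long deletions handled elsewhere; need an anchor
        anchor = run_start - 1
        window_len = min(1 + run_len, th.max_window)
        cols = list(range(anchor, anchor + window_len))

        ref_window = genome.sequence[anchor : anchor + window_len]
        survivors: list[str] | None = None
        for w in range(2, window_len + 1):
            sub_cols = cols[:w]
            per_site: list[list[str]] = []
            for col in sub_cols:
                site = pile.site_counts(col, qm, exclude_rows=excl)
                ref_b = genome.sequence[col]
                al = candidate_alleles(site, ref_b)
                al = [a for a in al if "+" not in a]  # anchored insertions excluded
                per_site.append(al)
            if survivors is not None:
                prefixes = set(survivors)
                per_site_alleles = [
                    [h + a for h in prefixes for a in per_site[-1]]
                ]
                cand = per_site_alleles[0]
            else:
                cand = [""]
                for al in per_site:
                    cand = [h + a for h in cand for a in al]
            cand = sorted(set(cand))

            rows = [
                int(r)
                for r in pile.rows_covering(sub_cols)
                if int(r) not in excl
            ]
            site = SiteCounts(anchor)
            for r in rows:
                hap = "".join(CHAR_OF[pile.codes[r, c]] for c in sub_cols)
                if hap not in cand:
                    continue
                qwin = pile.quals[r, sub_cols]
                q = int(qwin[qwin >= 0].min()) if (qwin >= 0).any() else qm.q_min
                if q < qm.q_min:
                    continue
                site.add(hap, pile.strands[r], q)
            ref_hap = genome.sequence[anchor : anchor + w]
            present = [a for a in cand if any(k[0] == a for k in site.counts)]
            if ref_hap not in present:
                present.insert(0, ref_hap)
            alleles = [ref_hap] + [a for a in present if a != ref_hap]
            cmat, errs, _ = _count_matrix(site, alleles, qm)
            f, se, ll, conv, _it = fit_frequencies(
                cmat, errs, tol=th.tol, max_iter=th.max_iter
            )
            survivors = [a for i, a in enumerate(alleles) if i == 0 or f[i] > 0]
            fit = FitResult(alleles, f, se, ll, conv, _it)
            last_site = site
        ests = lrt_qualities(fit, last_site, qm, th)
        kept = [
            (a, e)
            for a, e in zip(fit.alleles, ests)
            if a != ref_window[: len(a)] and e.f_hat > 0
        ]
        if kept:
            calls.append(
                MergedCall(
                    start=anchor,
                    ref=ref_window,
                    haplotypes=[a for a, _ in kept],
                    estimates=[e for _, e in kept],
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def filter_call(
    call: VariantCall,
    site: SiteCounts,
    thresholds: CallerThresholds | None = None,
) -> VariantCall:
    """Attach strand-bias, base-quality, quality and frequency flags.

    (a) two-sided Fisher exact test of minor vs major allele counts by
    strand; (b) one-sided Mann-Whitney test of minor-allele base
    qualities being lower than the major allele's; (c) phred LRT quality
    below ``qual_min_call``; plus a low-frequency flag below
    ``low_freq_threshold``.  Flags annotate, never delete.
    """
    th = thresholds or CallerThresholds()
    flags: set[str] = set()
    major = call.baseline or call.ref
    maj_f, maj_r = site.strand_counts(major)
    maj_quals = site.qualities(major)
    for est in call.estimates[1:]:
        alt = est.allele
        min_f, min_r = site.strand_counts(alt)
        if (maj_f + maj_r) > 0 and (min_f + min_r) > 0:
            _odds, p = stats.fisher_exact([[maj_f, maj_r], [min_f, min_r]])
            if p < th.p_strand:
                flags.add("strand_bias")
        min_quals = site.qualities(alt)
        if min_quals and maj_quals and (
            len(set(min_quals) | set(maj_quals)) > 1
        ):
            _u, p = stats.mannwhitneyu(min_quals, maj_quals, alternative="less")
            if p < th.p_qual:
                flags.add("base_qual_bias")
        if est.qual < th.qual_min_call:
            flags.add("low_qual")
        if est.f_hat < th.low_freq_threshold:
            flags.add("low_freq")
    call.filters = sorted(flags)
    return call


# ---------------------------------------------------------------------------
# Genome-wide calling and VCF output
# ---------------------------------------------------------------------------


def call_variants(
    pile: Pileup,
    genome: MitoGenome,
    qm: QualityModel | None = None,
    thresholds: CallerThresholds | None = None,
) -> tuple[list[VariantCall], list[DeletionAllele], list[MergedCall]]:
    """Run the full calling strategy on a pileup.

    Steps: long-deletion detection and clustering; per-site candidate
    detection and VAF estimation (excluding long-deletion carrier reads
    inside their regions); short-indel haplotype merging; statistical
    filtering.
    """
    qm = qm or QualityModel()
    th = thresholds or CallerThresholds()
    ref_codes = encode_seq(genome.sequence)

    dels, exclusions, regions = detect_long_deletions(pile, qm, th)
    in_region = np.zeros(pile.l, dtype=bool)
    region_rows = np.zeros(pile.l, dtype=object)
    for (start, length) in regions:
        rows = exclusions.get(start, set())
        for off in range(length):
            p = (start + off) % pile.l
            in_region[p] = True
            region_rows[p] = rows

    all_excluded = set().union(*exclusions.values()) if exclusions else set()
    merged = merge_indel_haplotypes(pile, genome, qm, th, exclude_rows=all_excluded)
    merged_cols = {
        c for mc in merged for c in range(mc.start, mc.start + len(mc.ref))
    }

    calls: list[VariantCall] = []
    for col in pile.candidate_columns(qm, ref_codes):
        col = int(col)
        if col in merged_cols:
            continue
        excl = region_rows[col] if in_region[col] else None
        site = pile.site_counts(col, qm, exclude_rows=excl)
        if site.depth() == 0:
            continue
        ref_b = genome.sequence[col]
        fit = estimate_vaf(site, qm, ref_b, th)
        alts = [
            a
            for i, a in enumerate(fit.alleles)
            if i > 0 and fit.f_hat[i] > 0 and a != ref_b
        ]
        # long deletions are reported separately, not as per-site del calls
        if in_region[col]:
            alts = [a for a in alts if a != DEL_ALLELE]
        if not alts and fit.alleles[0] == ref_b:
            continue
        ests = lrt_qualities(fit, site, qm, th)
        keep = [e for e in ests if e.allele in alts]
        if not keep:
            continue
        call = VariantCall(
            position=col,
            ref=ref_b,
            alts=[e.allele for e in keep],
            estimates=[ests[0]] + keep,
            depth_fwd={a: site.strand_counts(a)[0] for a in site.alleles()},
            depth_rev={a: site.strand_counts(a)[1] for a in site.alleles()},
            baseline=fit.alleles[0],
        )
        filter_call(call, site, th)
        calls.append(call)
    calls.sort(key=lambda c: c.position)
    return calls, dels, merged


def _vcf_header(sample: str, genome: MitoGenome) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={genome.name},length={genome.l}>",
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Maximum-likelihood variant allele fraction">',
        '##INFO=<ID=SE,Number=A,Type=Float,Description="Asymptotic standard error of AF">',
        '##INFO=<ID=LRT,Number=A,Type=Float,Description="Likelihood-ratio statistic for AF>0">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of a deletion">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Deletion length (negative)">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">',
        '##INFO=<ID=EVENT,Number=1,Type=String,Description="Shared event id for origin-spanning deletions">',
        '##FILTER=<ID=strand_bias,Description="Fisher exact test of allelic strand bias">',
        '##FILTER=<ID=base_qual_bias,Description="Mann-Whitney test of low minor-allele base quality">',
        '##FILTER=<ID=low_qual,Description="Phred-scaled LRT quality below threshold">',
        '##FILTER=<ID=low_freq,Description="VAF below the low-frequency threshold">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=ADF,Number=R,Type=Integer,Description="Forward-strand allele depths">',
        '##FORMAT=<ID=ADR,Number=R,Type=Integer,Description="Reverse-strand allele depths">',
        '##FORMAT=<ID=HF,Number=A,Type=Float,Description="Read-count heteroplasmy fraction: alt reads / spanning reads">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample,
    ]
    return "\n".join(lines) + "\n"


def write_vcf(
    calls: list[VariantCall],
    dels: list[DeletionAllele],
    merged: list[MergedCall],
    sample: str,
    genome: MitoGenome,
    path: str | Path,
) -> None:
    """Write all calls as a VCF 4.2 file with 1-based coordinates.

    SNV/indel records carry AF/SE/LRT in INFO and DP/ADF/ADR/HF in the
    sample column, where HF is the simple read-count heteroplasmy
    fraction (alt reads over reads spanning the position).  Long
    deletions are emitted as ``<DEL>`` records with END and SVLEN;
    origin-spanning deletions become two records sharing an EVENT id.
    """
    records: list[tuple[int, str]] = []
    for call in calls:
        pos1 = call.position + 1
        alts, refs = [], call.ref
        alt_strings = []
        for alt in call.alts:
            if alt == DEL_ALLELE:
                # represented against the previous base is not available at
                # site level; use symbolic allele
                alt_strings.append("<DEL>")
            elif alt.startswith(call.ref + "+") or "+" in alt:
                base, ins = alt.split("+", 1)
                alt_strings.append(base + ins)
            else:
                alt_strings.append(alt)
        ests = {e.allele: e for e in call.estimates}
        alt_ests = [ests[a] for a in call.alts]
        af = ",".join(f"{e.f_hat:.6g}" for e in alt_ests)
        se = ",".join(f"{e.se:.6g}" for e in alt_ests)
        lrt = ",".join(f"{e.lr_stat:.6g}" for e in alt_ests)
        qual = max((e.qual for e in alt_ests), default=0.0)
        depth = sum(call.depth_fwd.values()) + sum(call.depth_rev.values())
        alleles_out = [call.ref] + call.alts
        adf = ",".join(str(call.depth_fwd.get(a, 0)) for a in alleles_out)
        adr = ",".join(str(call.depth_rev.get(a, 0)) for a in alleles_out)
        hf = ",".join(
            f"{(call.depth_fwd.get(a, 0) + call.depth_rev.get(a, 0)) / depth:.6g}"
            if depth
            else "0"
            for a in call.alts
        )
        rec = (
            f"{genome.name}\t{pos1}\t.\t{refs}\t{','.join(alt_strings)}\t"
            f"{qual:.1f}\t{call.filter_field}\t"
            f"AF={af};SE={se};LRT={lrt}\tDP:ADF:ADR:HF\t{depth}:{adf}:{adr}:{hf}"
        )
        records.append((pos1, rec))
    for mc in merged:
        pos1 = mc.start + 1
        alt_strings = [h.replace("-", "") or "<DEL>" for h in mc.haplotypes]
        af = ",".join(f"{e.f_hat:.6g}" for e in mc.estimates)
        se = ",".join(f"{e.se:.6g}" for e in mc.estimates)
        lrt = ",".join(f"{e.lr_stat:.6g}" for e in mc.estimates)
        qual = max((e.qual for e in mc.estimates), default=0.0)
        filt = ";".join(mc.filters) if mc.filters else "PASS"
        rec = (
            f"{genome.name}\t{pos1}\t.\t{mc.ref}\t{','.join(alt_strings)}\t"
            f"{qual:.1f}\t{filt}\tAF={af};SE={se};LRT={lrt}\tDP\t."
        )
        records.append((pos1, rec))
    for k, da in enumerate(dels):
        if da.start + da.length <= genome.l:
            pieces = [(da.start, da.length)]
            event = ""
        else:
            first = genome.l - da.start
            pieces = [(da.start, first), (0, da.length - first)]
            event = f";EVENT=del{k}"
        for (s, ln) in pieces:
            # standard SV convention: POS is the base before the deleted
            # run, END the last deleted base (1-based)
            anchor1 = s if s > 0 else 1
            end = s + ln
            rec = (
                f"{genome.name}\t{anchor1}\t.\t{genome.sequence[anchor1 - 1]}\t<DEL>\t.\tPASS\t"
                f"AF={da.f_hat:.6g};SE={da.se:.6g};SVTYPE=DEL;END={end};SVLEN={anchor1 - end}{event}"
                f"\tDP\t{da.n_reads}"
            )
            records.append((anchor1, rec))
    records.sort(key=lambda r: r[0])
    with open(path, "w") as fh:
        fh.write(_vcf_header(sample, genome))
        for _pos, rec in records:
            fh.write(rec + "\n")


def write_coverage(pile: Pileup, genome: MitoGenome, path: str | Path) -> None:
    """Tab-separated per-base coverage (1-based position, depth)."""
    cov = pile.coverage()
    with open(path, "w") as fh:
        fh.write("contig\tposition\tdepth\n")
        for p in range(pile.l):
            fh.write(f"{genome.name}\t{p + 1}\t{int(cov[p])}\n")
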