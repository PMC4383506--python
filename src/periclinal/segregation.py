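"""Per-locus segregation analysis of selfed progenies and two-point linkage.

In an S1 (selfed) design, a locus heterozygous in the parent's L2 layer
segregates 1:2:1 for codominant alleles, or 3:1 for a dominant
presence/absence assay.  Departures are diagnostic: a locus whose two
parental gametes carry the same allele is FIXED in the progeny (the
hallmark of somatic replacement tracts), and a ~25% amplification-failure
class reveals hemizygosity — a null (deleted) allele carried by one
haplotype.  Insertion-site pairs are analyzed jointly (empty + full site),
which makes all three genotype classes distinguishable.

Two-point recombination fractions are estimated by maximum likelihood
(EM over the ambiguous double-heterozygote classes of the F2/S1 design)
and converted to map distances with Kosambi's (reporting default) or
Haldane's function.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .mapfun import MappingFunction, rf_to_cM
from .model import GenotypeTable, MarkerPanel, SampleGenotype

__all__ = [
    "SegClass",
    "LocusSegregation",
    "ChiSquareResult",
    "NullAlleleCall",
    "RecombinationEstimate",
    "classify_locus_segregation",
    "chi_square_gof",
    "detect_null_allele",
    "estimate_recombination_fraction",
]


class SegClass(str, enum.Enum):
    SEGREGATING = "SEGREGATING"
    FIXED = "FIXED"
    NULL_SEGREGATING = "NULL_SEGREGATING"
    MONOMORPHIC = "MONOMORPHIC"
    IRREGULAR = "IRREGULAR"


@dataclass
class LocusSegregation:
    marker: str
    alleles: tuple[str, ...]
    class_counts: dict[str, int]
    classification: SegClass
    n_informative: int

    @property
    def no_amp_count(self) -> int:
        return self.class_counts.get("no_amplification", 0)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class NullAlleleCall:
    hemizygous: bool
    null_frequency_hat: float
    p_value: float


@dataclass
class RecombinationEstimate:
    marker_a: str
    marker_b: str
    rf: float
    map_distance_cM: float
    n: int
    log_likelihood: float = float("nan")
    warnings: list[str] = field(default_factory=list)


def _label_key(label: str):
    return (0, int(label)) if label.isdigit() else (1, label)


def classify_locus_segregation(
    progeny: GenotypeTable,
    marker: str,
    parent_leaf: SampleGenotype | None = None,
    *,
    error_rate: float = 0.0,
    dropout_rate: float = 0.0,
) -> LocusSegregation:
    """Classify the progeny segregation pattern at one logical locus.

    A tolerance of ``floor(n * error_rate + 2)`` discordant calls is
    permitted when testing whether an allele is shown by "all" progeny;
    an allele must appear in more than ``floor(n * error_rate)`` progeny
    to count as observed, and an amplification-failure class larger than
    ``floor(n * dropout_rate)`` marks null-allele segregation.
    ``parent_leaf`` (whole-plant genotype) distinguishes FIXED at a locus
    heterozygous in the leaf — a chimera signal — from a MONOMORPHIC locus.
    """
    if marker not in progeny.panel:
        raise KeyError(f"marker {marker!r} not in panel")
    calls = [s.call(marker) for s in progeny]
    calls = [c for c in calls if not c.missing]
    n = len(calls)
    if n == 0:
        raise ValueError(f"no progeny with data at {marker!r}")
    tol = math.floor(n * error_rate + 2)
    tol_pres = math.floor(n * error_rate)
    tol_noamp = math.floor(n * dropout_rate)

    no_amp = sum(1 for c in calls if c.no_amplification)
    presence: dict[str, int] = {}
    for c in calls:
        for lab in c.alleles:
            presence[lab] = presence.get(lab, 0) + 1

    parent_alleles = None
    if parent_leaf is not None and not parent_leaf.call(marker).missing:
        parent_alleles = set(parent_leaf.call(marker).alleles)

    if parent_alleles is not None:
        non_parental = {lab: k for lab, k in presence.items() if lab not in parent_alleles}
    else:
        non_parental = {}
    observed = sorted(
        (lab for lab in presence if lab not in non_parental), key=_label_key
    )

    a = observed[0] if observed else None
    b = observed[1] if len(observed) > 1 else None
    counts = {
        "hom_a": sum(1 for c in calls if c.alleles == frozenset({a})) if a else 0,
        "het": sum(1 for c in calls if a and b and c.alleles == frozenset({a, b})),
        "hom_b": sum(1 for c in calls if b and c.alleles == frozenset({b})) or 0,
        "no_amplification": no_amp,
    }
    counts["other"] = n - sum(counts.values())

    if sum(non_parental.values()) > tol or len(observed) > 2:
        cls = SegClass.IRREGULAR
    elif len(observed) == 0:
        cls = SegClass.IRREGULAR
    elif len(observed) == 1:
        if no_amp > tol_noamp:
            cls = SegClass.NULL_SEGREGATING
        elif parent_alleles is not None and len(parent_alleles) >= 2:
            cls = SegClass.FIXED
        else:
            cls = SegClass.MONOMORPHIC
    else:
        absent_a = n - presence[a]
        absent_b = n - presence[b]
        if absent_a <= tol and absent_b <= tol:
            cls = SegClass.FIXED  # the allele pair is shown by all progeny
        elif min(presence[a], presence[b]) > tol_pres and no_amp <= tol:
            # both alleles transmitted; an empty homozygote class at small
            # n is ordinary sampling, not an irregularity
            cls = SegClass.SEGREGATING
        else:
            cls = SegClass.IRREGULAR
    return LocusSegregation(marker, tuple(observed), counts, cls, n)


def chi_square_gof(observed, expected_ratio) -> ChiSquareResult:
    """Pearson goodness-of-fit of observed counts against a ratio (e.g. 1:2:1)."""
    obs = np.asarray(observed, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if obs.shape != ratio.shape:
        raise ValueError("observed and expected_ratio must have the same length")
    if obs.sum() <= 0:
        raise ValueError("total observed count must be > 0")
    if np.any(ratio <= 0):
        raise ValueError("ratio weights must be > 0")
    expected = ratio / ratio.sum() * obs.sum()
    stat, p = stats.chisquare(obs, expected)
    return ChiSquareResult(float(stat), len(obs) - 1, float(p))


def detect_null_allele(seg: LocusSegregation, alpha: float = 0.05) -> NullAlleleCall:
    """Test whether an amplification-failure class fits the 1/4 null/null expectation.

    Under selfing of an A/null parent, 25% of offspring inherit null/null
    and fail to amplify.  The locus is called hemizygous when a nonzero
    no-amplification class is consistent with p = 0.25 (exact binomial
    test not rejected at ``alpha``).
    """
    if seg.n_informative < 10:
        raise ValueError("null-allele detection needs >= 10 informative progeny")
    k, n = seg.no_amp_count, seg.n_informative
    p_value = stats.binomtest(k, n, 0.25).pvalue
    return NullAlleleCall(
        hemizygous=k > 0 and p_value >= alpha,
        null_frequency_hat=k / n,
        p_value=float(p_value),
    )


# ---------------------------------------------------------------------------
# two-point linkage


def _locus_gamete_states(progeny: GenotypeTable, marker: str) -> tuple:
    """The two parental gamete states at a locus, inferred from progeny calls.

    Returns a (state0, state1) tuple where a state is an allele label or
    None (a null allele, revealed by an amplification-failure class).
    """
    calls = [s.call(marker) for s in progeny if not s.call(marker).missing]
    labels = sorted({lab for c in calls for lab in c.alleles}, key=_label_key)
    no_amp = sum(1 for c in calls if c.no_amplification)
    if len(labels) == 2:
        return labels[0], labels[1]
    if len(labels) == 1 and no_amp > 0:
        return labels[0], None
    raise ValueError(
        f"locus {marker!r} is not segregating (alleles {labels}, {no_amp} amplification failures)"
    )


def _observation(states: tuple, p1: int, p2: int) -> frozenset:
    labels = {states[p1], states[p2]} - {None}
    return frozenset(labels)


def _em_rf(class_counts: dict, states_a: tuple, states_b: tuple) -> tuple[float, float]:
    """EM estimate of rf under a fixed phase pairing; returns (rf, loglik)."""
    # 16 ordered gamete pairs; gamete = (phase_at_a, phase_at_b).  For each
    # observable two-locus class, precompute the compatible gamete pairs as
    # (# recombinant gametes in the pair, # gametes recombinant per term).
    gametes = [(ga, gb) for ga in (0, 1) for gb in (0, 1)]
    compat: dict[tuple, list[tuple[int, int]]] = {}
    for t1 in gametes:
        for t2 in gametes:
            obs = (
                _observation(states_a, t1[0], t2[0]),
                _observation(states_b, t1[1], t2[1]),
            )
            rec = (t1[0] != t1[1]) + (t2[0] != t2[1])
            compat.setdefault(obs, []).append((rec, 0))
    # collapse to per-class recombinant-count multiplicities
    terms: list[tuple[int, tuple[int, int, int]]] = []  # (count, (m0, m1, m2))
    for key, count in class_counts.items():
        mult = [0, 0, 0]
        for rec, _ in compat.get(key, []):
            mult[rec] += 1
        if sum(mult):
            terms.append((count, tuple(mult)))
    n = sum(class_counts.values())
    r = 0.25
    for _ in range(500):
        par, rec = (1 - r) / 2, r / 2
        # gamete-pair prob with k recombinant gametes: par^(2-k) * rec^k
        w = [par * par, par * rec, rec * rec]
        exp_rec = 0.0
        for count, (m0, m1, m2) in terms:
            total = m0 * w[0] + m1 * w[1] + m2 * w[2]
            if total > 0:
                exp_rec += count * (m1 * w[1] + 2 * m2 * w[2]) / total
        r_new = min(max(exp_rec / (2 * n), 1e-12), 0.5)
        if abs(r_new - r) < 1e-10:
            r = r_new
            break
        r = r_new
    par, rec = (1 - r) / 2, r / 2
    w = [par * par, par * rec, rec * rec]
    loglik = 0.0
    for count, (m0, m1, m2) in terms:
        total = m0 * w[0] + m1 * w[1] + m2 * w[2]
        loglik += count * math.log(total) if total > 0 else float("-inf")
    return r, loglik


def estimate_recombination_fraction(
    progeny: GenotypeTable,
    marker_a: str,
    marker_b: str,
    mapping_function: MappingFunction = MappingFunction.KOSAMBI,
) -> RecombinationEstimate:
    """Two-point ML recombination fraction between two segregating loci.

    The likelihood is maximized by EM over the gamete configurations
    compatible with each observed two-locus genotype class (the
    double-heterozygote class mixes parental and recombinant gamete
    pairs).  Both phase pairings are evaluated and the higher-likelihood
    one kept, as S1 data alone do not label the parental haplotypes.
    """
    states_a = _locus_gamete_states(progeny, marker_a)
    states_b = _locus_gamete_states(progeny, marker_b)
    class_counts: dict[tuple, int] = {}
    n = 0
    for s in progeny:
        ca, cb = s.call(marker_a), s.call(marker_b)
        if ca.missing or cb.missing:
            continue
        key = (ca.alleles, cb.alleles)
        class_counts[key] = class_counts.get(key, 0) + 1
        n += 1
    warnings = []
    if n < 20:
        warnings.append(f"only {n} informative progeny; estimate is unreliable")
    best = None
    for sb in (states_b, states_b[::-1]):
        r, ll = _em_rf(class_counts, states_a, sb)
        if best is None or ll > best[1]:
            best = (r, ll)
    rf, loglik = best
    rf = min(rf, 0.5)
    return RecombinationEstimate(
        marker_a=marker_a,
        marker_b=marker_b,
        rf=rf,
        map_distance_cM=rf_to_cM(rf, mapping_function),
        n=n,
        log_likelihood=loglik,
        warnings=warnings,
    )
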