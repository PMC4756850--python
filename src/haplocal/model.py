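"""Bayesian local-haplotype presence model.

A segment of R proximal SNVs admits L = 2^R candidate haplotypes (the
Cartesian product of the two alleles at each SNV). The sample's haplotype
content is a binary presence vector lambda = (lambda_1, ..., lambda_L);
fragments are modelled as draws from a uniform mixture over the present
haplotypes, with per-base sequencing error e_ir (an observed base agrees
with the emitting haplotype with probability 1 - e_ir and takes each of the
other three bases with probability e_ir / 3; missing bases carry no
information under the MCAR assumption). Each lambda_j carries an independent
Beta-Bernoulli prior whose marginal presence probability is
alpha / (alpha + beta).

Because L <= 8 when R <= 3, the posterior over all 2^L presence
configurations is computed exactly: each configuration's joint probability
is evaluated once (in log space) and the marginal presence posteriors
xi_j = Pr(lambda_j = 1 | data) are assembled by summing the configuration
table over the index sets that fix bit j. Haplotypes are then selected by
thresholding the posterior expected FDR of the top-t set at f0; a segment
whose selected set exceeds two haplotypes is impossible for a homogeneous
diploid population and is flagged as a local haplotype variant (LHV).

The model/results pair follows the statsmodels convention:
``LocalHaplotypeModel(...).fit()`` returns a :class:`LocalHaplotypeResults`
with estimates, the selection, and a ``summary()`` table.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .reads import MISSING, FragmentObservation, PatternCounts, collapse_patterns
from .segments import SegmentDef

__all__ = [
    "CandidateHaplotype",
    "ModelParams",
    "LocalHaplotypeModel",
    "LocalHaplotypeResults",
    "enumerate_haplotypes",
    "fragment_loglik",
    "prior_presence_prob",
    "config_logprior",
    "joint_config_table",
    "index_set",
    "decimal_index",
    "lambdas_from_index",
    "posterior_presence",
    "fdr_select",
    "call_segment",
    "brute_force_posterior",
]

R_MAX_EXACT = 3  # L = 8, 256 presence configurations


@dataclass(frozen=True)
class CandidateHaplotype:
    """Candidate haplotype j (1-based) with sequence over the segment's SNVs."""

    j: int
    seq: str


@dataclass(frozen=True)
class ModelParams:
    """Prior and decision parameters.

    alpha, beta
        Beta shape parameters of the Beta-Bernoulli presence prior; the
        marginal prior presence probability is alpha / (alpha + beta)
        (0.05 / 1.05 ~ 4.8% at the defaults — a weak prior that a random
        candidate haplotype is present).
    f0
        Posterior-expected-FDR threshold for selecting haplotypes.
    e_mode, e_const
        Base-error handling: ``constant`` uses e_const everywhere; ``phred``
        uses per-base qualities recorded during extraction.
    """

    alpha: float = 0.05
    beta: float = 1.0
    f0: float = 0.01
    e_mode: str = "constant"
    e_const: float = 0.001

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not 0 < self.f0 < 1:
            raise ValueError(f"f0 must lie in (0,1), got {self.f0}")
        if not 0 < self.e_const < 0.75:
            raise ValueError(f"e_const must lie in (0, 0.75), got {self.e_const}")
        if self.e_mode not in ("constant", "phred"):
            raise ValueError(f"unknown e_mode {self.e_mode!r}")


def enumerate_haplotypes(segment: SegmentDef) -> list[CandidateHaplotype]:
    """All 2^R candidate haplotypes in fixed order.

    SNV 1 is the most significant choice bit with ref=0 < alt=1, so the
    first haplotype is all-ref and the last all-alt.
    """
    if not segment.analyzed or segment.R > R_MAX_EXACT:
        raise ValueError(
            f"segment with R={segment.R} SNVs exceeds the exact-inference limit "
            f"R <= {R_MAX_EXACT}; mark it not-analyzed"
        )
    pairs = [(s.ref, s.alt) for s in segment.snvs]
    return [
        CandidateHaplotype(j + 1, "".join(combo))
        for j, combo in enumerate(itertools.product(*pairs))
    ]


def fragment_loglik(obs: FragmentObservation, hap: CandidateHaplotype | str) -> float:
    """Log-probability of one fragment's observed bases given a haplotype.

    Agreeing bases contribute log(1-e_ir), disagreeing ones log(e_ir/3);
    missing positions contribute 0 because the sum over the four possible
    hidden bases of (1-e) + 3*(e/3) is exactly 1.
    """
    seq = hap.seq if isinstance(hap, CandidateHaplotype) else hap
    total = 0.0
    for s, h, e in zip(obs.calls, seq, obs.errors):
        if s == MISSING:
            continue
        total += math.log1p(-e) if s == h else math.log(e / 3.0)
    return total


def prior_presence_prob(alpha: float, beta: float) -> float:
    """Marginal Beta-Bernoulli presence probability, via the Gamma form.

    Evaluates Gamma(1+a)Gamma(b)/Gamma(1+a+b) * Gamma(a+b)/(Gamma(a)Gamma(b))
    and checks it agrees with the algebraic simplification a/(a+b).
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    log_p = (
        gammaln(1 + alpha)
        + gammaln(beta)
        - gammaln(1 + alpha + beta)
        + gammaln(alpha + beta)
        - gammaln(alpha)
        - gammaln(beta)
    )
    p = float(np.exp(log_p))
    assert abs(p - alpha / (alpha + beta)) < 1e-12
    return p


def decimal_index(lambdas: tuple[int, ...] | list[int]) -> int:
    """Decimal index of a presence configuration, lambda_1 as the MSB."""
    idx = 0
    for lam in lambdas:
        if lam not in (0, 1):
            raise ValueError("lambdas must be binary")
        idx = (idx << 1) | lam
    return idx


def lambdas_from_index(l: int, L: int) -> tuple[int, ...]:
    """Inverse of :func:`decimal_index` for vectors of length L."""
    if not 0 <= l < (1 << L):
        raise ValueError(f"index {l} out of range for L={L}")
    return tuple((l >> (L - 1 - k)) & 1 for k in range(L))


def index_set(j: int, value: int, L: int) -> frozenset[int]:
    """Configuration indices l whose MSB-first bit j (1-based) equals value."""
    if not 1 <= j <= L:
        raise ValueError(f"haplotype index {j} outside 1..{L}")
    if value not in (0, 1):
        raise ValueError("value must be 0 or 1")
    shift = L - j
    return frozenset(l for l in range(1 << L) if ((l >> shift) & 1) == value)


def config_logprior(lambdas: tuple[int, ...], params: ModelParams) -> float:
    """Log prior of a presence configuration (independent Beta-Bernoulli)."""
    p = prior_presence_prob(params.alpha, params.beta)
    n1 = sum(lambdas)
    return n1 * math.log(p) + (len(lambdas) - n1) * math.log1p(-p)


def _pattern_logliks(
    patterns: PatternCounts,
    haps: list[CandidateHaplotype],
    params: ModelParams,
    errors_by_pattern: dict[str, tuple[float, ...]] | None = None,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-pattern, per-haplotype log-likelihood matrix and count vector."""
    pats = sorted(patterns.counts)
    counts = np.array([patterns.counts[p] for p in pats], dtype=float)
    ll = np.empty((len(pats), len(haps)))
    for a, pat in enumerate(pats):
        errs = (
            errors_by_pattern[pat]
            if errors_by_pattern is not None
            else (params.e_const,) * len(pat)
        )
        obs = FragmentObservation(fragment_id=pat, calls=pat, errors=errs)
        for b, hap in enumerate(haps):
            ll[a, b] = fragment_loglik(obs, hap)
    return pats, counts, ll


def joint_config_table(
    patterns: PatternCounts,
    haps: list[CandidateHaplotype],
    params: ModelParams,
    errors_by_pattern: dict[str, tuple[float, ...]] | None = None,
) -> np.ndarray:
    """Normalized posterior over all 2^L presence configurations.

    For configuration C_l with n >= 1 present haplotypes, the fragment
    likelihood is the uniform mixture (1/n) * sum over present haplotypes;
    identical fragments enter as a single pattern raised to its count. The
    all-absent configuration has likelihood zero (no haplotype can emit a
    read) and loses its prior mass to the normalization. Computed in log
    space with log-sum-exp; each configuration is evaluated exactly once.
    """
    L = len(haps)
    if patterns.N < 1:
        raise ValueError("joint_config_table requires at least one fragment")
    _, counts, ll = _pattern_logliks(patterns, haps, params, errors_by_pattern)

    log_joint = np.full(1 << L, -np.inf)
    for l in range(1, 1 << L):
        lambdas = lambdas_from_index(l, L)
        present = [k for k, lam in enumerate(lambdas) if lam]
        # logsumexp over present haplotypes per pattern, minus log n
        mix = logsumexp(ll[:, present], axis=1) - math.log(len(present))
        log_joint[l] = float(counts @ mix) + config_logprior(lambdas, params)
    return np.exp(log_joint - logsumexp(log_joint))


def posterior_presence(joint: np.ndarray, L: int) -> np.ndarray:
    """Marginal presence posteriors xi_j from the configuration table.

    Each configuration probability is computed once and shared across all
    2L marginal sums via the bit-fixing index sets.
    """
    if joint.shape[0] != (1 << L):
        raise ValueError("joint table length must be 2^L")
    xi = np.empty(L)
    for j in range(1, L + 1):
        idx = np.fromiter(index_set(j, 1, L), dtype=int)
        xi[j - 1] = joint[idx].sum()
    return np.clip(xi, 0.0, 1.0)


def fdr_select(xi: np.ndarray, f0: float) -> list[int]:
    """Largest top-t set whose posterior expected FDR stays below f0.

    Sorts xi in decreasing order (ties broken by haplotype index, for
    determinism), computes the running mean of (1 - xi), and keeps the
    largest t with mean < f0. Returns the selected haplotype indices
    (1-based), ascending; empty if even the best haplotype fails.
    """
    if not 0 < f0 < 1:
        raise ValueError(f"f0 must lie in (0,1), got {f0}")
    order = np.argsort(-xi, kind="stable")
    running = np.cumsum(1.0 - xi[order]) / np.arange(1, len(xi) + 1)
    admissible = np.nonzero(running < f0)[0]
    if admissible.size == 0:
        return []
    t_star = int(admissible[-1]) + 1
    return sorted(int(j) + 1 for j in order[:t_star])


@dataclass
class LocalHaplotypeResults:
    """Fitted presence posteriors and the FDR-selected haplotype set."""

    model: "LocalHaplotypeModel"
    xi: np.ndarray
    joint: np.ndarray | None
    selected: tuple[int, ...]
    params: ModelParams

    @property
    def haplotypes(self) -> list[CandidateHaplotype]:
        return self.model.haplotypes

    @property
    def n_significant(self) -> int:
        return len(self.selected)

    @property
    def is_lhv(self) -> bool:
        """More than two present haplotypes: evidence of somatic mosaicism."""
        return self.n_significant >= 3

    @property
    def selected_sequences(self) -> tuple[str, ...]:
        by_j = {h.j: h.seq for h in self.haplotypes}
        return tuple(by_j[j] for j in self.selected)

    def xi_for(self, seq: str) -> float:
        for h, x in zip(self.haplotypes, self.xi):
            if h.seq == seq:
                return float(x)
        raise KeyError(f"no candidate haplotype {seq!r}")

    def summary(self) -> pd.DataFrame:
        sel = set(self.selected)
        return pd.DataFrame(
            {
                "haplotype": [h.seq for h in self.haplotypes],
                "xi": np.round(self.xi, 6),
                "significant": [h.j in sel for h in self.haplotypes],
            },
            index=pd.Index([h.j for h in self.haplotypes], name="j"),
        )

    def __repr__(self) -> str:
        calls = ", ".join(
            f"{s}:{self.xi_for(s):.2f}" for s in self.selected_sequences
        ) or "none"
        tag = "LHV" if self.is_lhv else "no variant"
        return f"<LocalHaplotypeResults [{calls}] ({tag})>"


class LocalHaplotypeModel:
    """Exact Bayesian model of haplotype presence within one SNV segment.

    Built either from fragment observations (:meth:`from_observations`) or
    directly from collapsed read-pattern counts (:meth:`from_patterns`).
    ``fit()`` evaluates the full configuration posterior and applies the
    FDR selection rule.
    """

    def __init__(
        self,
        segment: SegmentDef,
        patterns: PatternCounts,
        params: ModelParams | None = None,
        errors_by_pattern: dict[str, tuple[float, ...]] | None = None,
    ) -> None:
        self.segment = segment
        self.patterns = patterns
        self.params = params or ModelParams()
        self.errors_by_pattern = errors_by_pattern
        self.haplotypes = enumerate_haplotypes(segment)

    @classmethod
    def from_observations(
        cls,
        segment: SegmentDef,
        observations: list[FragmentObservation],
        params: ModelParams | None = None,
    ) -> "LocalHaplotypeModel":
        params = params or ModelParams()
        obs = [
            o if o.errors is not None else replace(o, errors=(params.e_const,) * segment.R)
            for o in observations
        ]
        errors_by_pattern: dict[str, tuple[float, ...]] = {}
        for o in obs:
            prev = errors_by_pattern.setdefault(o.calls, o.errors)
            if params.e_mode == "constant" and prev != o.errors:
                raise ValueError("pattern collapse requires pattern-constant errors")
        return cls(segment, collapse_patterns(obs), params, errors_by_pattern)

    @classmethod
    def from_patterns(
        cls,
        segment: SegmentDef,
        counts: dict[str, int],
        params: ModelParams | None = None,
    ) -> "LocalHaplotypeModel":
        return cls(segment, PatternCounts(dict(counts)), params)

    def fit(self) -> LocalHaplotypeResults:
        L = len(self.haplotypes)
        if self.patterns.N == 0:
            # no usable fragments: report zero significant haplotypes
            return LocalHaplotypeResults(
                self, np.zeros(L), None, (), self.params
            )
        joint = joint_config_table(
            self.patterns, self.haplotypes, self.params, self.errors_by_pattern
        )
        xi = posterior_presence(joint, L)
        selected = tuple(fdr_select(xi, self.params.f0))
        return LocalHaplotypeResults(self, xi, joint, selected, self.params)


def call_segment(
    segment: SegmentDef,
    observations: list[FragmentObservation],
    params: ModelParams | None = None,
) -> LocalHaplotypeResults:
    """Convenience wrapper: observations -> fitted results for one segment."""
    return LocalHaplotypeModel.from_observations(segment, observations, params).fit()


# ---------------------------------------------------------------------------
# naive oracle — used only in tests


def _explicit_marginal_lik(
    calls: str, errors: tuple[float, ...], hap_seq: str, e_missing: float
) -> float:
    """Fragment likelihood with the hidden bases summed out explicitly.

    Enumerates every completion b in {A,C,G,T}^w of the missing positions and
    sums the full-length agree/disagree products — no factor-1 shortcut.
    """
    missing_idx = [r for r, s in enumerate(calls) if s == MISSING]
    total = 0.0
    for completion in itertools.product("ACGT", repeat=len(missing_idx)):
        full = list(calls)
        for r, b in zip(missing_idx, completion):
            full[r] = b
        term = 1.0
        for r, (s, h) in enumerate(zip(full, hap_seq)):
            e = e_missing if r in missing_idx else errors[r]
            term *= (1.0 - e) if s == h else e / 3.0
        total += term
    return total


def brute_force_posterior(
    observations: list[FragmentObservation],
    segment: SegmentDef,
    params: ModelParams | None = None,
) -> np.ndarray:
    """xi_j by the naive nested sum over all partner configurations.

    For each haplotype j, sums the unnormalized joint over the 2^(L-1)
    configurations of the remaining indicators with lambda_j fixed at 1 and
    at 0, in linear space, with explicit marginalization of missing bases.
    Independent of the fast path; intended as a test oracle at tiny N.
    """
    params = params or ModelParams()
    haps = enumerate_haplotypes(segment)
    L = len(haps)
    obs = [
        o if o.errors is not None else replace(o, errors=(params.e_const,) * segment.R)
        for o in observations
    ]

    # the explicit marginal depends only on (calls, errors, haplotype)
    marginal: dict[tuple[str, tuple[float, ...], int], float] = {}
    for o in obs:
        for k in range(L):
            key = (o.calls, o.errors, k)
            if key not in marginal:
                marginal[key] = _explicit_marginal_lik(
                    o.calls, o.errors, haps[k].seq, params.e_const
                )

    config_cache: dict[tuple[int, ...], float] = {}

    def config_lik(lambdas: tuple[int, ...]) -> float:
        if lambdas in config_cache:
            return config_cache[lambdas]
        present = [k for k, lam in enumerate(lambdas) if lam]
        if not present:
            lik = 0.0
        else:
            lik = 1.0
            for o in obs:
                lik *= sum(
                    marginal[(o.calls, o.errors, k)] for k in present
                ) / len(present)
        config_cache[lambdas] = lik
        return lik

    xi = np.empty(L)
    for j in range(L):
        num = 0.0
        denom = 0.0
        for partner in itertools.product((0, 1), repeat=L - 1):
            for lam_j in (1, 0):
                lambdas = partner[:j] + (lam_j,) + partner[j:]
                contrib = config_lik(lambdas) * math.exp(
                    config_logprior(lambdas, params)
                )
                denom += contrib
                if lam_j == 1:
                    num += contrib
        xi[j] = num / denom
    return xi
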