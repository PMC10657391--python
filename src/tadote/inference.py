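"""Segregation tests and likelihood inference from genotype count tables.

Two estimation problems arise from toxin-antidote cross data:

* the killing efficiency ``k`` of a locus, identified by the leak-through of
  the killed allele class in self or testcross progeny of a heterozygote
  (``k = 1`` predicts a 1:1 self ratio with no null homozygotes; ``k < 1``
  lets a small fraction through);
* the female joint-gamete transmission weights ``w`` in the stacked
  two-locus F2, where the male gamete is fixed by complete killing and the
  four progeny classes map one-to-one onto female gamete classes (saturated
  multinomial, so the MLE is the vector of sample proportions).

Class probabilities are always computed from the crossing model at the
candidate parameter value, never hard-coded, so the likelihood inherits the
model's assumptions exactly.
"""
from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .crossing import GenotypeDistribution, cross, self_progeny
from .model import InputError, Panel, ValidationError
from .panel import (
    default_panel,
    double_heterozygote,
    gamete_key,
    genotype_key,
    homozygote,
    parse_genotype,
    single_locus_panel,
)

__all__ = [
    "CountTable",
    "FitResult",
    "SegregationTestResult",
    "segregation_test",
    "fit_killing_efficiency",
    "fit_female_weights",
    "goodness_of_fit_report",
    "invert_dd_proportion",
    "self_het_class_probs",
]


@dataclass
class CountTable:
    """Observed genotype-class counts from one cross design."""

    counts: dict
    design: str = "custom"

    def __post_init__(self) -> None:
        for k, v in self.counts.items():
            iv = int(v)
            if iv != v or iv < 0:
                raise InputError(f"count for class {k!r} must be a nonnegative integer")
            self.counts[k] = iv
        if self.n <= 0:
            raise InputError("count table is empty (total n must be > 0)")

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_tsv(cls, path: Union[str, Path], design: str = "custom") -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        if not {"class", "count"} <= set(df.columns):
            raise InputError(f"count table {path} must have columns 'class' and 'count'")
        return cls(dict(zip(df["class"].astype(str), df["count"])), design=design)

    def to_tsv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(
            {"class": list(self.counts), "count": list(self.counts.values())}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class SegregationTestResult:
    chi2: float
    df: int
    pvalue: float
    n: int
    exact_pvalue: Optional[float] = None
    method: str = "pearson_chi2"


@dataclass
class FitResult:
    """Estimator output: point estimates, log-likelihood, 95% CIs."""

    estimates: dict
    loglik: float
    ci: dict
    method: str
    converged: bool
    n: int
    design: str
    boundary: tuple = ()
    extras: dict = field(default_factory=dict)

    def to_json(self, path: Optional[Union[str, Path]] = None) -> str:
        payload = {
            "estimates": self.estimates,
            "loglik": self.loglik,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "method": self.method,
            "converged": self.converged,
            "n": self.n,
            "design": self.design,
            "boundary": list(self.boundary),
            "extras": self.extras,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


# ---------------------------------------------------------------------------
# segregation test


def _align(observed: CountTable, expected_probs) -> tuple[list, np.ndarray, np.ndarray]:
    labels = list(observed.counts)
    obs = np.array([observed.counts[l] for l in labels], dtype=float)
    if isinstance(expected_probs, dict):
        missing = [l for l in labels if l not in expected_probs]
        if missing:
            raise ValidationError(f"expected probabilities missing classes {missing}")
        extra = [l for l in expected_probs if l not in labels]
        if extra:
            raise ValidationError(f"expected probabilities have unknown classes {extra}")
        probs = np.array([expected_probs[l] for l in labels], dtype=float)
    else:
        probs = np.asarray(expected_probs, dtype=float)
        if probs.shape != obs.shape:
            raise ValidationError(
                f"{len(labels)} observed classes but {probs.size} expected probabilities"
            )
    if probs.min() < 0 or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
        raise ValidationError("expected probabilities must be nonnegative and sum to 1")
    return labels, obs, probs


def _exact_multinomial_pvalue(obs: np.ndarray, probs: np.ndarray, max_enum: int) -> Optional[float]:
    n = int(obs.sum())
    k = obs.size
    if math.comb(n + k - 1, k - 1) > max_enum:
        return None
    from scipy.special import gammaln

    vecs = np.array(
        [
            np.bincount(np.array(c, dtype=int), minlength=k)
            for c in itertools.combinations_with_replacement(range(k), n)
        ],
        dtype=float,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        logp_terms = np.where(vecs > 0, vecs * np.log(probs), 0.0)
        impossible = np.any((probs == 0.0) & (vecs > 0), axis=1)
    logpmf = (
        gammaln(n + 1) - gammaln(vecs + 1).sum(axis=1) + logp_terms.sum(axis=1)
    )
    logpmf[impossible] = -np.inf
    obs_idx = np.all(vecs == obs, axis=1)
    obs_logp = float(logpmf[obs_idx][0]) if obs_idx.any() else -np.inf
    if obs_logp == -np.inf:
        return 0.0
    # probability-ordering exact test: sum pmf over outcomes no more likely
    # than the observed one
    mask = logpmf <= obs_logp + 1e-9
    return float(min(np.exp(logpmf[mask]).sum(), 1.0))


def segregation_test(
    observed: CountTable,
    expected_probs,
    exact_max_n: int = 200,
    max_enumeration: int = 2_000_000,
) -> SegregationTestResult:
    """Pearson chi-square test of observed counts against expected ratios.

    No continuity correction; df = number of classes - 1.  When the total
    count is small (``n <= exact_max_n``) an exact multinomial tail
    probability (probability-ordering test) is computed by enumeration and
    reported alongside.  A class with expected probability 0 but a positive
    observed count yields an infinite statistic with the exact test as
    fallback.
    """
    labels, obs, probs = _align(observed, expected_probs)
    n = int(obs.sum())
    keep = probs > 0.0
    df = int(keep.sum()) - 1  # classes outside the multinomial support carry no df
    zero_conflict = bool(np.any(~keep & (obs > 0)))
    if zero_conflict:
        chi2, pvalue = math.inf, 0.0
        method = "pearson_chi2_infinite"
    else:
        expected = n * probs[keep]
        chi2 = float(((obs[keep] - expected) ** 2 / expected).sum())
        pvalue = float(stats.chi2.sf(chi2, df))
        method = "pearson_chi2"
    exact = None
    if n <= exact_max_n:
        exact = _exact_multinomial_pvalue(obs, probs, max_enumeration)
    return SegregationTestResult(
        chi2=chi2,
        df=df,
        pvalue=pvalue if not zero_conflict else (exact if exact is not None else 0.0),
        n=n,
        exact_pvalue=exact,
        method=method,
    )


# ---------------------------------------------------------------------------
# killing-efficiency estimation


def self_het_class_probs(k: float, locus_id: str = "qHMS1", base: Optional[Panel] = None) -> dict:
    """Progeny class probabilities for the self of a single-locus heterozygote.

    Closed form (derived from the model and used here through the crossing
    machinery): P(func/func) = 1/(2(2-k)), P(het) = 1/2,
    P(null/null) = (1-k)/(2(2-k)).
    """
    sub = single_locus_panel(locus_id, k=k, base=base)
    het = double_heterozygote(sub)
    return dict(self_progeny(het, sub).items())


def invert_dd_proportion(p: float) -> float:
    """Moment inversion of the null-homozygote proportion in a het self.

    Solves p = (1-k)/(2(2-k)) for k: k = (1-4p)/(1-2p), clipped to [0, 1].
    This is the method-of-moments estimate from the single leak-through
    class; :func:`fit_killing_efficiency` maximizes the full multinomial
    likelihood instead.
    """
    if not 0.0 <= p <= 1.0:
        raise InputError(f"proportion must lie in [0, 1], got {p!r}")
    if p >= 0.5:
        return 0.0
    return min(1.0, max(0.0, (1.0 - 4.0 * p) / (1.0 - 2.0 * p)))


def _design_distribution(design: str, k: float, locus_id: str, base: Optional[Panel]) -> GenotypeDistribution:
    sub = single_locus_panel(locus_id, k=k, base=base)
    het = double_heterozygote(sub)
    if design == "self_het":
        return self_progeny(het, sub)
    if design == "testcross":
        return cross(homozygote(sub, "fa"), het, sub)
    raise ValidationError(f"no killing-efficiency likelihood for design {design!r}")


def _canonical_labels(labels: Sequence[str], locus_id: str, base: Optional[Panel]) -> dict:
    """Map user class labels (e.g. 'M/M') onto canonical genotype keys."""
    sub = single_locus_panel(locus_id, base=base)
    mapping = {}
    for lab in labels:
        try:
            mapping[lab] = genotype_key(parse_genotype(lab, sub), sub)
        except InputError:
            mapping[lab] = lab
    return mapping


def fit_killing_efficiency(
    observed: CountTable,
    design: Optional[str] = None,
    locus_id: str = "qHMS1",
    panel: Optional[Panel] = None,
    ci_level: float = 0.95,
) -> FitResult:
    """Maximum-likelihood estimate of the killing efficiency ``k``.

    The multinomial class probabilities are computed from the crossing model
    at each candidate ``k`` (designs: ``self_het``, ``testcross``); the MLE
    is found numerically on [0, 1] and the confidence interval by profile
    likelihood at the chi-square(1) cutoff.  Boundary estimates (typically
    ``k = 1`` when the null-homozygote count is 0) are flagged and reported
    with one-sided intervals.
    """
    design = design or observed.design
    label_map = _canonical_labels(list(observed.counts), locus_id, panel)
    counts = {}
    for lab, c in observed.counts.items():
        key = label_map[lab]
        counts[key] = counts.get(key, 0) + c
    model_keys = set(_design_distribution(design, 0.5, locus_id, panel).entries)
    unknown = set(counts) - model_keys
    if unknown:
        raise ValidationError(
            f"observed classes {sorted(unknown)} not predicted by design "
            f"{design!r} (expected {sorted(model_keys)})"
        )
    labels = sorted(model_keys)
    obs = np.array([counts.get(l, 0) for l in labels], dtype=float)
    n = int(obs.sum())

    def loglik(k: float) -> float:
        dist = _design_distribution(design, k, locus_id, panel)
        ll = 0.0
        for l, c in zip(labels, obs):
            p = dist.probability(l)
            if c > 0:
                if p <= 0.0:
                    return -math.inf
                ll += c * math.log(p)
        return ll

    res = optimize.minimize_scalar(
        lambda k: -loglik(k), bounds=(0.0, 1.0), method="bounded",
        options={"xatol": 1e-10},
    )
    candidates = [(loglik(0.0), 0.0), (loglik(1.0), 1.0), (-res.fun, float(res.x))]
    best_ll, k_hat = max(candidates, key=lambda t: t[0])
    boundary = []
    if k_hat >= 1.0 - 1e-8:
        k_hat = 1.0
        boundary.append("k=1")
    elif k_hat <= 1e-8:
        k_hat = 0.0
        boundary.append("k=0")
    best_ll = loglik(k_hat)

    cutoff = stats.chi2.ppf(ci_level, 1) / 2.0
    target = best_ll - cutoff

    def _edge(lo: float, hi: float) -> float:
        f = lambda k: loglik(k) - target
        return float(optimize.brentq(f, lo, hi, xtol=1e-10))

    eps = 1e-12
    if k_hat > 0.0 and loglik(0.0) < target:
        ci_lo = _edge(0.0, k_hat)
    else:
        ci_lo = 0.0
    if k_hat < 1.0 and loglik(1.0 - eps) < target:
        ci_hi = _edge(k_hat, 1.0 - eps)
    elif k_hat < 1.0:
        ci_hi = 1.0
    else:
        ci_hi = 1.0
    if k_hat == 1.0 and loglik(1.0) >= target:
        # one-sided interval up to the boundary
        ci_lo = _edge(0.0, 1.0) if loglik(0.0) < target else 0.0

    return FitResult(
        estimates={"k": k_hat},
        loglik=best_ll,
        ci={"k": (ci_lo, ci_hi)},
        method="ml_profile_likelihood",
        converged=bool(res.success),
        n=n,
        design=design,
        boundary=tuple(boundary),
    )


# ---------------------------------------------------------------------------
# female transmission weights


def f2_gamete_class_map(panel: Optional[Panel] = None) -> dict:
    """Map F2 genotype keys onto the female gamete classes producing them.

    Valid for the stacked double heterozygote with complete killing, where
    the male gamete is the single all-functional class.
    """
    panel = panel if panel is not None else default_panel()
    panel = panel.with_killing_efficiency(1.0)
    het = double_heterozygote(panel)
    from .crossing import female_gamete_classes
    from .model import male_gamete_distribution

    male = male_gamete_distribution(het, panel).surviving()
    if len(male) != 1:
        raise ValidationError(
            "female-weight design requires a single surviving male gamete class"
        )
    mg = male[0]
    mapping = {}
    for hap, carried, _f in female_gamete_classes(het, panel):
        from .crossing import _offspring

        child = _offspring(hap, carried, mg.haplotype, mg.transgenes_carried)
        mapping[genotype_key(child, panel)] = gamete_key(hap, panel)
    return mapping


def fit_female_weights(
    observed: CountTable,
    panel: Optional[Panel] = None,
    seed: Optional[int] = None,
    n_boot: int = 1000,
    ci_level: float = 0.95,
) -> FitResult:
    """MLE of female joint-gamete transmission weights in the stacked F2.

    The four-class multinomial is saturated, so the MLE is the vector of
    sample proportions.  A likelihood-ratio test against the uniform
    1:1:1:1 null (df = 3) is reported; nonparametric bootstrap percentile
    CIs are computed when a ``seed`` is supplied (reproducibility requires
    it).  Absent classes get weight 0 with a boundary flag.
    """
    panel = panel if panel is not None else default_panel()
    mapping = f2_gamete_class_map(panel)
    label_map = {}
    for lab in observed.counts:
        if lab in mapping:
            label_map[lab] = mapping[lab]
        elif lab in mapping.values():
            label_map[lab] = lab
        else:
            try:
                key = genotype_key(parse_genotype(lab, panel), panel)
            except InputError:
                key = lab
            if key not in mapping:
                raise ValidationError(
                    f"class {lab!r} is not an F2 genotype of the stacked design "
                    f"(expected one of {sorted(mapping)})"
                )
            label_map[lab] = mapping[key]
    gamete_classes = sorted(set(mapping.values()))
    counts = {g: 0 for g in gamete_classes}
    for lab, c in observed.counts.items():
        counts[label_map[lab]] += c
    obs = np.array([counts[g] for g in gamete_classes], dtype=float)
    n = int(obs.sum())
    w_hat = obs / n

    pos = obs > 0  # 0*log(0) terms contribute nothing
    ll = float(np.sum(obs[pos] * np.log(w_hat[pos])))
    lrt = float(2.0 * np.sum(obs[pos] * np.log(w_hat[pos] / 0.25)))
    lrt_p = float(stats.chi2.sf(lrt, df=len(gamete_classes) - 1))
    boundary = tuple(g for g, c in counts.items() if c == 0)

    ci = {}
    if seed is not None:
        rng = np.random.default_rng(seed)
        boots = rng.multinomial(n, w_hat, size=n_boot) / n
        alpha = (1.0 - ci_level) / 2.0
        lo = np.quantile(boots, alpha, axis=0)
        hi = np.quantile(boots, 1.0 - alpha, axis=0)
        ci = {g: (float(l), float(h)) for g, l, h in zip(gamete_classes, lo, hi)}
        for g in boundary:
            ci[g] = (0.0, ci[g][1])  # one-sided at the w=0 boundary

    return FitResult(
        estimates={g: float(w) for g, w in zip(gamete_classes, w_hat)},
        loglik=ll,
        ci=ci,
        method="multinomial_mle_bootstrap",
        converged=True,
        n=n,
        design="f2_double_het",
        boundary=boundary,
        extras={"lrt_stat": lrt, "lrt_df": len(gamete_classes) - 1, "lrt_pvalue": lrt_p},
    )


# ---------------------------------------------------------------------------
# goodness of fit


def goodness_of_fit_report(
    observed: CountTable,
    expected: Union[GenotypeDistribution, dict],
) -> tuple[pd.DataFrame, SegregationTestResult]:
    """Join observed counts with model-expected counts; residuals + overall test."""
    probs = dict(expected.items()) if isinstance(expected, GenotypeDistribution) else dict(expected)
    obs_classes = set(observed.counts)
    missing = obs_classes - set(probs)
    if missing:
        raise ValidationError(f"model prediction lacks observed classes {sorted(missing)}")
    full = {k: probs.get(k, 0.0) for k in sorted(set(probs) | obs_classes)}
    n = observed.n
    rows = []
    for k in full:
        o = observed.counts.get(k, 0)
        e = n * full[k]
        rows.append(
            {
                "class": k,
                "observed": o,
                "expected": e,
                "residual": o - e,
                "pearson_residual": (o - e) / math.sqrt(e) if e > 0 else math.inf if o else 0.0,
            }
        )
    table = CountTable({k: observed.counts.get(k, 0) for k in full}, design=observed.design)
    test = segregation_test(table, {k: full[k] for k in full})
    return pd.DataFrame(rows), test
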