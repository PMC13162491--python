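"""Mutation-class-corrected Ka/Ks estimation from catalog counts.

Four quantities are computed from the observed per-class mutation counts
(s_i synonymous, n_i non-synonymous with nonsense included) and the per-class
substitution-opportunity totals (S_i, N_i) of the reference CDS set:

* ``crude``            —  Σn_i / Σs_i  (raw counts, no per-site normalisation)
* ``uncorrected``      —  (Σn_i/ΣN_i) / (Σs_i/ΣS_i)
* ``corrected_syn``    —  Σn_i / Σ_i(N_i·s_i/S_i)    (bias correction via synonymous sites)
* ``corrected_nonsyn`` —  Σ_i(S_i·n_i/N_i) / Σs_i    (bias correction via non-synonymous sites)

The two corrected estimators reweight one category's observed counts by the
other category's per-class opportunity ratio, so that a mutational spectrum
skewed toward particular substitution classes (e.g. transition-biased
mutagenesis in aged colonies) does not masquerade as selection.  Under the
generative model of :mod:`colonyevo.simulate` both corrected estimators have
expectation equal to the non-synonymous acceptance probability omega.

Classes with no synonymous opportunity (S_i = 0, hence necessarily s_i = 0)
contribute a 0/0 term to ``corrected_syn``; they are excluded and recorded
rather than propagated as NaN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .catalog import SpectrumCounts
from .codon import MutationClass, SiteCountTable


class UndefinedRatioError(ZeroDivisionError):
    """A Ka/Ks quantity is undefined for these inputs (zero denominator)."""


def _check(counts: SpectrumCounts, sites: SiteCountTable | None):
    for m in MutationClass:
        if counts.s[m] < 0 or counts.n[m] < 0:
            raise ValueError(f"negative count for class {m.value}")
        if sites is not None and (sites.S[m] < 0 or sites.N[m] < 0):
            raise ValueError(f"negative site total for class {m.value}")


def kaks_crude(counts: SpectrumCounts) -> float:
    """Raw count ratio Σn / Σs (no per-site normalisation)."""
    _check(counts, None)
    total_s = counts.total_s()
    if total_s == 0:
        raise UndefinedRatioError("crude Ka/Ks undefined: no synonymous mutations (Σs = 0)")
    return counts.total_n() / total_s


def kaks_uncorrected(counts: SpectrumCounts, sites: SiteCountTable) -> float:
    """(Σn/ΣN) / (Σs/ΣS): per-site rates, no spectrum correction."""
    _check(counts, sites)
    sum_N = sum(sites.N.values())
    sum_S = sum(sites.S.values())
    sum_s = counts.total_s()
    if sum_N == 0:
        raise UndefinedRatioError("uncorrected Ka/Ks undefined: ΣN = 0")
    if sum_S == 0:
        raise UndefinedRatioError("uncorrected Ka/Ks undefined: ΣS = 0")
    if sum_s == 0:
        raise UndefinedRatioError("uncorrected Ka/Ks undefined: Σs = 0")
    return (counts.total_n() / sum_N) / (sum_s / sum_S)


def kaks_corrected_syn(
    counts: SpectrumCounts, sites: SiteCountTable
) -> tuple[float, list[tuple[MutationClass, str]]]:
    """Σn / Σ(N_i·s_i/S_i), excluding degenerate classes with S_i = 0.

    Returns the ratio and the list of excluded classes with reasons.
    """
    _check(counts, sites)
    denom = 0.0
    excluded = []
    for m in MutationClass:
        if sites.S[m] == 0:
            if counts.s[m] > 0:
                raise ValueError(
                    f"class {m.value} has s_i={counts.s[m]} but S_i=0: "
                    "counts inconsistent with the site table"
                )
            excluded.append((m, "S_i = 0 (no synonymous opportunity); 0/0 term dropped"))
            continue
        denom += sites.N[m] * counts.s[m] / sites.S[m]
    if denom == 0:
        raise UndefinedRatioError(
            "corrected (synonymous-site) Ka/Ks undefined: Σ(N_i·s_i/S_i) = 0"
        )
    return counts.total_n() / denom, excluded


def kaks_corrected_nonsyn(
    counts: SpectrumCounts, sites: SiteCountTable
) -> tuple[float, list[tuple[MutationClass, str]]]:
    """Σ(S_i·n_i/N_i) / Σs, excluding degenerate classes with N_i = n_i = 0."""
    _check(counts, sites)
    total_s = counts.total_s()
    if total_s == 0:
        raise UndefinedRatioError(
            "corrected (non-synonymous-site) Ka/Ks undefined: Σs = 0"
        )
    numer = 0.0
    excluded = []
    for m in MutationClass:
        if sites.N[m] == 0:
            if counts.n[m] > 0:
                raise UndefinedRatioError(
                    f"class {m.value} has n_i={counts.n[m]} but N_i=0: "
                    "counts inconsistent with the site table"
                )
            excluded.append((m, "N_i = 0 (no non-synonymous opportunity); 0/0 term dropped"))
            continue
        numer += sites.S[m] * counts.n[m] / sites.N[m]
    return numer / total_s, excluded


@dataclass
class KaKsResult:
    """Bundle of the four Ka/Ks quantities; undefined components are flagged."""

    crude: float | None = None
    uncorrected: float | None = None
    corrected_syn: float | None = None
    corrected_nonsyn: float | None = None
    undefined: dict = field(default_factory=dict)
    excluded_classes: dict = field(default_factory=dict)

    def to_json(self, path=None):
        payload = {
            "crude": self.crude,
            "uncorrected": self.uncorrected,
            "corrected_syn": self.corrected_syn,
            "corrected_nonsyn": self.corrected_nonsyn,
            "undefined": self.undefined,
            "excluded_classes": {
                name: [(m.value, reason) for m, reason in items]
                for name, items in self.excluded_classes.items()
            },
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return payload


def kaks_all(counts: SpectrumCounts, sites: SiteCountTable) -> KaKsResult:
    """Compute all four quantities; per-component errors become flags, not aborts."""
    result = KaKsResult()
    try:
        result.crude = kaks_crude(counts)
    except (UndefinedRatioError, ValueError) as exc:
        result.undefined["crude"] = str(exc)
    try:
        result.uncorrected = kaks_uncorrected(counts, sites)
    except (UndefinedRatioError, ValueError) as exc:
        result.undefined["uncorrected"] = str(exc)
    try:
        result.corrected_syn, exc_syn = kaks_corrected_syn(counts, sites)
        if exc_syn:
            result.excluded_classes["corrected_syn"] = exc_syn
    except (UndefinedRatioError, ValueError) as exc:
        result.undefined["corrected_syn"] = str(exc)
    try:
        result.corrected_nonsyn, exc_non = kaks_corrected_nonsyn(counts, sites)
        if exc_non:
            result.excluded_classes["corrected_nonsyn"] = exc_non
    except (UndefinedRatioError, ValueError) as exc:
        result.undefined["corrected_nonsyn"] = str(exc)
    return result


class KaKsModel:
    """Ka/Ks estimation from observed spectrum counts and a site-count table.

    Parameters
    ----------
    counts
        Observed per-class synonymous / non-synonymous mutation counts.
    sites
        Per-class substitution-opportunity totals over the reference CDS set.

    ``fit()`` returns a :class:`KaKsResults` carrying the four point
    estimates; ``fit(bootstrap=B)`` adds percentile bootstrap intervals
    obtained by resampling the observed mutations with replacement.
    """

    def __init__(self, counts: SpectrumCounts, sites: SiteCountTable):
        self.counts = counts
        self.sites = sites

    @classmethod
    def from_catalog(cls, records, sites: SiteCountTable) -> "KaKsModel":
        from .catalog import tally_spectrum

        return cls(tally_spectrum(records), sites)

    def fit(self, bootstrap: int = 0, seed: int | None = None) -> "KaKsResults":
        point = kaks_all(self.counts, self.sites)
        ci = None
        if bootstrap:
            ci = self._bootstrap(bootstrap, seed)
        return KaKsResults(self, point, bootstrap_ci=ci, n_bootstrap=bootstrap)

    def _bootstrap(self, n_boot: int, seed):
        rng = np.random.default_rng(seed)
        # one categorical outcome per observed mutation: (class, is_syn)
        outcomes = []
        for m in MutationClass:
            outcomes += [(m, True)] * self.counts.s[m]
            outcomes += [(m, False)] * self.counts.n[m]
        n_mut = len(outcomes)
        if n_mut == 0:
            return None
        draws = {"crude": [], "uncorrected": [], "corrected_syn": [], "corrected_nonsyn": []}
        for _ in range(n_boot):
            idx = rng.integers(0, n_mut, n_mut)
            resampled = SpectrumCounts()
            for i in idx:
                m, is_syn = outcomes[i]
                if is_syn:
                    resampled.s[m] += 1
                else:
                    resampled.n[m] += 1
            res = kaks_all(resampled, self.sites)
            for name in draws:
                value = getattr(res, name)
                if value is not None:
                    draws[name].append(value)
        ci = {}
        for name, values in draws.items():
            if values:
                lo, hi = np.percentile(values, [2.5, 97.5])
                ci[name] = (float(lo), float(hi), len(values))
        return ci


class KaKsResults:
    """Fitted Ka/Ks estimates with optional bootstrap intervals."""

    def __init__(self, model: KaKsModel, result: KaKsResult, bootstrap_ci=None, n_bootstrap=0):
        self.model = model
        self.result = result
        self.bootstrap_ci = bootstrap_ci
        self.n_bootstrap = n_bootstrap

    def __getattr__(self, name):
        if name in ("crude", "uncorrected", "corrected_syn", "corrected_nonsyn",
                    "undefined", "excluded_classes"):
            return getattr(self.result, name)
        raise AttributeError(name)

    def summary(self) -> str:
        counts = self.model.counts
        lines = [
            "Ka/Ks estimation",
            "=" * 48,
            f"observed mutations: {counts.total_n()} non-synonymous, "
            f"{counts.total_s()} synonymous",
            "",
            f"{'estimator':<28}{'value':>10}",
            "-" * 38,
        ]
        labels = {
            "crude": "crude (Σn/Σs)",
            "uncorrected": "per-site, uncorrected",
            "corrected_syn": "corrected (syn sites)",
            "corrected_nonsyn": "corrected (non-syn sites)",
        }
        for name, label in labels.items():
            value = getattr(self.result, name)
            if value is None:
                lines.append(f"{label:<28}{'undefined':>10}")
            else:
                lines.append(f"{label:<28}{value:>10.2f}")
        for name, items in self.result.excluded_classes.items():
            for m, reason in items:
                lines.append(f"  [{name}] excluded class {m.value}: {reason}")
        for name, reason in self.result.undefined.items():
            lines.append(f"  [{name}] undefined: {reason}")
        if self.bootstrap_ci:
            lines.append("")
            lines.append(f"bootstrap 95% percentile intervals (B={self.n_bootstrap}):")
            for name, (lo, hi, nb) in self.bootstrap_ci.items():
                lines.append(f"  {labels[name]:<28}[{lo:.2f}, {hi:.2f}]")
        return "\n".join(lines)

    def to_json(self, path=None):
        payload = self.result.to_json()
        if self.bootstrap_ci:
            payload["bootstrap_ci"] = {
                k: {"lower": lo, "upper": hi, "n_defined": nb}
                for k, (lo, hi, nb) in self.bootstrap_ci.items()
            }
            payload["n_bootstrap"] = self.n_bootstrap
        if path is not None:
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=2)
        return payload
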