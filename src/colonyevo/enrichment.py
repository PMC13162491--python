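"""Hypergeometric gene-set overlap: observed k, expectation, fold, tail p.

Given a gene module of size n, a target set of size K and a universe of N
genes, the overlap k is compared with the hypergeometric expectation
n*K/N; the reported probability is the exact upper tail P[X >= k] under
Hypergeometric(N, K, n), accumulated in log space so extremely small p
(down to ~1e-300) remain representable.  The universe is a required explicit
input: it is never inferred from the union of the two sets, because the
result is sensitive to N.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp


@dataclass
class EnrichmentResult:
    n_module: int
    n_targets: int
    n_universe: int
    overlap: int
    expected: float
    fold: float
    p_upper: float
    p_lower: float | None = None
    overlap_genes: tuple = ()

    def to_json(self, path=None):
        payload = {
            "n_module": self.n_module,
            "n_targets": self.n_targets,
            "n_universe": self.n_universe,
            "overlap": self.overlap,
            "expected": self.expected,
            "fold": self.fold,
            "p_upper": self.p_upper,
            "p_lower": self.p_lower,
            "overlap_genes": sorted(self.overlap_genes),
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return payload

    def to_text(self) -> str:
        lines = [
            f"module size (n)     : {self.n_module}",
            f"target set size (K) : {self.n_targets}",
            f"universe size (N)   : {self.n_universe}",
            f"overlap (k)         : {self.overlap}",
            f"expected (n*K/N)    : {self.expected:.2f}",
            f"fold enrichment     : {self.fold:.2f}",
            f"P[X >= k]           : {self.p_upper:.3g}",
        ]
        if self.p_lower is not None:
            lines.append(f"P[X <= k]           : {self.p_lower:.3g}")
        return "\n".join(lines)


def _upper_tail_log(k: int, N: int, K: int, n: int) -> float:
    """Exact P[X >= k] via log-space accumulation of hypergeometric pmf terms."""
    if k <= 0:
        return 1.0
    hi = min(n, K)
    if k > hi:
        return 0.0
    support = np.arange(k, hi + 1)
    logs = stats.hypergeom.logpmf(support, N, K, n)
    return float(np.exp(min(logsumexp(logs), 0.0)))


def hypergeom_overlap(
    module,
    targets,
    universe,
    overlap: int | None = None,
    depletion_tail: bool = False,
) -> EnrichmentResult:
    """Hypergeometric overlap of a gene module with a target set.

    ``module`` and ``targets`` are gene sets (or integer sizes, in which case
    ``overlap`` must be given); ``universe`` is a gene set or the integer N.
    Membership containment is validated when sets are supplied.
    """
    overlap_genes: tuple = ()
    if isinstance(universe, int):
        N = universe
    else:
        universe = set(universe)
        N = len(universe)
    if N <= 0:
        raise ValueError("empty universe")

    if isinstance(module, int):
        n = module
    else:
        module = set(module)
        if not isinstance(universe, int) and not module <= universe:
            raise ValueError(
                f"module contains {len(module - universe)} genes outside the universe"
            )
        n = len(module)
    if isinstance(targets, int):
        K = targets
    else:
        targets = set(targets)
        if not isinstance(universe, int) and not targets <= universe:
            raise ValueError(
                f"target set contains {len(targets - universe)} genes outside the universe"
            )
        K = len(targets)
    if n > N or K > N:
        raise ValueError(f"set sizes (n={n}, K={K}) exceed universe N={N}")

    if isinstance(module, set) and isinstance(targets, set):
        shared = module & targets
        if overlap is not None and overlap != len(shared):
            raise ValueError(
                f"supplied overlap {overlap} disagrees with computed {len(shared)}"
            )
        k = len(shared)
        overlap_genes = tuple(sorted(shared))
    else:
        if overlap is None:
            raise ValueError("overlap count required when sets are given as sizes")
        k = overlap
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"overlap k={k} outside feasible range 0..{min(n, K)}")

    expected = n * K / N
    fold = k / expected if expected > 0 else float("nan")
    p_upper = _upper_tail_log(k, N, K, n)
    p_lower = float(stats.hypergeom.cdf(k, N, K, n)) if depletion_tail else None
    return EnrichmentResult(
        n_module=n, n_targets=K, n_universe=N, overlap=k,
        expected=expected, fold=fold, p_upper=p_upper, p_lower=p_lower,
        overlap_genes=overlap_genes,
    )


def read_gene_list(path) -> list[str]:
    """Newline-delimited gene list; blank lines and '#' comments skipped."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
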