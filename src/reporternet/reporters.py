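"""Reporter-features scoring of transcription factors and receptors.

A regulator ("feature") is scored by aggregating the significance of its
measured network neighbors. Gene p-values p_g are converted to upper-tail
normal scores Z_g = Phi^{-1}(1 - p_g); a feature with k measured neighbors
gets

    Z_feature = (sum of neighbor Z_g) / sqrt(k)

which is then background-corrected against random gene sets of the same
size, drawn without replacement from the full measured-gene Z pool:

    Z_corrected = (Z_feature - mu_k) / sigma_k

with mu_k, sigma_k the Monte-Carlo mean and standard deviation of the
aggregate over ``n_samples`` random draws (cached per k, seeded). The
feature p-value is 1 - Phi(Z_corrected); BH adjustment runs across
features, and features with adjusted p below ``alpha`` (default 0.001) are
reported as significant. TF-target and receptor-protein networks are scored
identically; only the edge source differs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

_P_EPS = 1e-15  # clamp before quantile inversion so Z stays finite


@dataclass
class BipartiteNetwork:
    """Directed feature -> gene edges (TF-target or receptor-protein)."""

    targets: dict[str, set[str]]  # feature -> gene neighbors
    mode: str = "tf_target"  # or "receptor_protein"

    @property
    def features(self) -> list[str]:
        return sorted(self.targets)

    def restricted(self, genes: set[str]) -> "BipartiteNetwork":
        """Keep only edges to measured genes; drop features left neighborless."""
        kept = {
            f: inter
            for f, targets in self.targets.items()
            if (inter := targets & genes)
        }
        dropped = len(self.targets) - len(kept)
        if dropped:
            logger.info("dropped %d feature(s) with no measured neighbors", dropped)
        return BipartiteNetwork(kept, mode=self.mode)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in sorted(self.targets):
                for g in sorted(self.targets[f]):
                    fh.write(f"{f}\t{g}\n")


def load_bipartite(path: str | Path, mode: str = "tf_target") -> BipartiteNetwork:
    """Load a feature -> gene TSV (TRRUST-style; extra columns ignored)."""
    targets: dict[str, set[str]] = {}
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: need feature and target columns")
            targets.setdefault(parts[0].strip(), set()).add(parts[1].strip())
            n += 1
    if n == 0:
        raise ValueError(f"{path}: no edges found")
    return BipartiteNetwork(targets, mode=mode)


def gene_zscores(pvals: pd.Series) -> pd.Series:
    """Upper-tail normal scores Z_g = Phi^{-1}(1 - p_g), clamped to stay finite."""
    p = pvals.dropna()
    n_missing = len(pvals) - len(p)
    if n_missing:
        logger.warning("skipping %d gene(s) without a p-value", n_missing)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    clipped = np.clip(p.to_numpy(dtype=float), _P_EPS, 1.0 - _P_EPS)
    return pd.Series(stats.norm.isf(clipped), index=p.index, name="z")


def aggregate_feature(z: pd.Series, neighbors: set[str]) -> tuple[int, float]:
    """Aggregate neighbor Z scores: (k, sum / sqrt(k)) over measured neighbors."""
    members = [g for g in neighbors if g in z.index]
    k = len(members)
    if k == 0:
        raise ValueError("feature has no measured neighbors")
    return k, float(z.loc[members].sum() / np.sqrt(k))


class BackgroundSampler:
    """Monte-Carlo null for aggregate scores of random same-size gene sets.

    Draws ``n_samples`` gene sets of size k without replacement from the Z
    pool, caches (mu_k, sigma_k) per k, and is fully determined by its seed.
    """

    def __init__(self, z_pool: np.ndarray, n_samples: int = 100_000, seed: int = 0):
        if n_samples < 1000:
            raise ValueError("n_samples must be >= 1000 for a stable background")
        self.pool = np.asarray(z_pool, dtype=float)
        if self.pool.size == 0:
            raise ValueError("empty Z pool")
        self.n_samples = int(n_samples)
        self.seed = int(seed)
        self._cache: dict[int, tuple[float, float]] = {}

    def moments(self, k: int) -> tuple[float, float]:
        if k < 1 or k > self.pool.size:
            raise ValueError(f"k={k} outside [1, pool size {self.pool.size}]")
        if k not in self._cache:
            self._cache[k] = self._simulate(k)
        return self._cache[k]

    def _simulate(self, k: int) -> tuple[float, float]:
        # child stream per k so cached moments don't depend on request order
        rng = np.random.default_rng(np.random.SeedSequence((self.seed, k)))
        n_pool = self.pool.size
        if k == 1:
            idx = rng.integers(0, n_pool, size=self.n_samples)[:, None]
        elif k * (k - 1) / (2.0 * n_pool) < 0.5:
            # rejection sampling: redraw rows containing a repeated index
            idx = rng.integers(0, n_pool, size=(self.n_samples, k))
            bad = self._has_dup(idx)
            while bad.any():
                idx[bad] = rng.integers(0, n_pool, size=(int(bad.sum()), k))
                bad = self._has_dup(idx)
        else:
            # dense pools: per-chunk argpartition of random keys
            rows = []
            chunk = max(1, int(2e7) // n_pool)
            done = 0
            while done < self.n_samples:
                m = min(chunk, self.n_samples - done)
                keys = rng.random((m, n_pool))
                rows.append(np.argpartition(keys, k - 1, axis=1)[:, :k])
                done += m
            idx = np.vstack(rows)
        sums = self.pool[idx].sum(axis=1) / np.sqrt(k)
        mu = float(sums.mean())
        sigma = float(sums.std(ddof=1))
        if sigma == 0:
            raise ValueError("degenerate Z pool: background standard deviation is zero")
        return mu, sigma

    @staticmethod
    def _has_dup(idx: np.ndarray) -> np.ndarray:
        s = np.sort(idx, axis=1)
        return (s[:, 1:] == s[:, :-1]).any(axis=1)

    def correct(self, z_agg: float, k: int) -> float:
        mu, sigma = self.moments(k)
        return (z_agg - mu) / sigma


def background_correct(
    z_agg: float,
    k: int,
    z_pool: np.ndarray,
    n_samples: int = 100_000,
    seed: int = 0,
) -> float:
    """One-shot background correction (see :class:`BackgroundSampler`)."""
    return BackgroundSampler(z_pool, n_samples=n_samples, seed=seed).correct(z_agg, k)


def score_reporters(
    gene_pvalues: pd.Series,
    net: BipartiteNetwork,
    alpha: float = 0.001,
    n_samples: int = 100_000,
    seed: int = 0,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Score every feature of a bipartite network against gene significance.

    Parameters
    ----------
    gene_pvalues
        Per-gene unadjusted p-values over ALL measured genes (the background
        pool must represent the transcriptome, not just the DEGs). For
        multi-dataset designs combine per-dataset p-values first (e.g.
        :func:`reporternet.diffexpr.fisher_combine`).
    net
        TF-target or receptor-protein network.
    use_adjusted
        Significance by BH-adjusted p (default) or by raw p.

    Returns
    -------
    DataFrame indexed by feature with columns k, z_agg, z_corrected, p,
    p_adj, significant; sorted by p ascending, ties by feature id.
    """
    z = gene_zscores(gene_pvalues)
    restricted = net.restricted(set(z.index))
    if not restricted.targets:
        raise ValueError("no feature has measured neighbors after restriction")
    sampler = BackgroundSampler(z.to_numpy(), n_samples=n_samples, seed=seed)
    rows = []
    for feature in restricted.features:
        k, z_agg = aggregate_feature(z, restricted.targets[feature])
        z_corr = sampler.correct(z_agg, k)
        rows.append((feature, k, z_agg, z_corr, float(stats.norm.sf(z_corr))))
    table = pd.DataFrame(
        rows, columns=["feature", "k", "z_agg", "z_corrected", "p"]
    ).set_index("feature")
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    crit = table["p_adj"] if use_adjusted else table["p"]
    table["significant"] = crit < alpha
    table = table.assign(_id=table.index.astype(str)).sort_values(
        ["p", "_id"], kind="stable"
    )
    return table.drop(columns="_id")
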