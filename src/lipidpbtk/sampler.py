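"""Blockwise random-walk Metropolis sampler and convergence diagnostics.

Proposals are isotropic Gaussians per block (parameters that must stay
positive are sampled on the log scale by the callers).  Proposal scales are
tuned toward a target acceptance rate during burn-in only — the chain after
burn-in is a fixed-kernel Metropolis chain, so detailed balance holds for
every retained sample.  The target acceptance defaults to 10%, which was
found to mix best for this kind of high-dimensional PBTK posterior.

Posterior evaluations can be supplied either as a plain callable
``f(x) -> float`` or as a *stateful* block posterior implementing
``full(x)``, ``propose(x_new, block_index)``, ``accept()`` and ``reject()``
— the stateful form lets the model cache per-rat ODE solutions and
re-simulate only the rats a block actually touches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["metropolis_run", "gelman_rubin", "ChainState"]


class _CallableAdapter:
    """Wrap a plain log-posterior callable in the stateful protocol."""

    def __init__(self, f):
        self._f = f

    def full(self, x):
        return float(self._f(x))

    def propose(self, x_new, block):
        return float(self._f(x_new))

    def accept(self):
        pass

    def reject(self):
        pass


@dataclass
class ChainState:
    """One Metropolis chain: samples, log-posterior trace, tuning state."""

    samples: np.ndarray  # (n_iter, n_params)
    log_posterior: np.ndarray  # (n_iter,)
    accept_rate: np.ndarray  # per block, over the post-adaptation phase
    scales: np.ndarray  # final (frozen) proposal scales per block
    seed: int | None
    n_adapt: int
    blocks: list[np.ndarray] = field(default_factory=list)

    def burned(self, burn_frac: float = 0.4) -> np.ndarray:
        return self.samples[int(self.samples.shape[0] * burn_frac) :]


def metropolis_run(
    logpost,
    x0: np.ndarray,
    n_iter: int,
    blocks: list | None = None,
    scales: np.ndarray | float = 0.1,
    target_acceptance: float = 0.10,
    seed: int | None = None,
    adapt_frac: float = 0.4,
    adapt_interval: int = 50,
) -> ChainState:
    """Run one blockwise random-walk Metropolis chain.

    Parameters
    ----------
    logpost : callable or stateful block posterior
        Plain ``f(x) -> float`` or an object with ``full``/``propose``/
        ``accept``/``reject`` (see module docstring).
    x0 : array
        Initial parameter vector; the chain starts here.
    n_iter : int
        Number of full sweeps (every block updated once per sweep).
    blocks : list of index arrays, optional
        Defaults to a single block containing every parameter.
    scales : float or array
        Initial proposal SD per block.
    target_acceptance : float
        Acceptance rate the adaptation steers toward during burn-in
        (first ``adapt_frac`` of the sweeps); scales are frozen afterwards.
    seed : int, optional
        Seed for the proposal/acceptance RNG; a fixed seed reproduces the
        chain exactly.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    x = np.array(x0, dtype=float).copy()
    n_params = x.size
    if blocks is None:
        blocks = [np.arange(n_params)]
    blocks = [np.asarray(b, dtype=int) for b in blocks]
    n_blocks = len(blocks)
    scales = np.full(n_blocks, float(scales)) if np.isscalar(scales) else np.array(
        scales, dtype=float
    )
    if scales.size != n_blocks or np.any(scales <= 0):
        raise ValueError("one positive proposal scale per block is required")

    post = logpost if hasattr(logpost, "propose") else _CallableAdapter(logpost)
    rng = np.random.default_rng(seed)
    cur_lp = post.full(x)
    if not np.isfinite(cur_lp):
        raise ValueError("initial state has non-finite log-posterior")

    n_adapt = int(adapt_frac * n_iter)
    samples = np.empty((n_iter, n_params))
    lps = np.empty(n_iter)
    acc_window = np.zeros(n_blocks)
    acc_total = np.zeros(n_blocks)
    n_total = 0
    consecutive_rejects = 0
    warned = False

    for it in range(n_iter):
        any_accept = False
        for b, idx in enumerate(blocks):
            xp = x.copy()
            xp[idx] += rng.normal(0.0, scales[b], size=idx.size)
            lp = post.propose(xp, b)
            if np.log(rng.random()) < lp - cur_lp:
                x, cur_lp = xp, lp
                post.accept()
                acc_window[b] += 1
                any_accept = True
                if it >= n_adapt:
                    acc_total[b] += 1
            else:
                post.reject()
        if it >= n_adapt:
            n_total += 1
        consecutive_rejects = 0 if any_accept else consecutive_rejects + 1
        if consecutive_rejects >= 1000 and not warned:
            warnings.warn(
                "all Metropolis proposals rejected for 1000 consecutive sweeps",
                RuntimeWarning,
            )
            warned = True
        if it < n_adapt and (it + 1) % adapt_interval == 0:
            rate = acc_window / adapt_interval
            # Robbins-Monro step toward the target, damped over burn-in
            step = min(0.5, 2.0 / np.sqrt(1.0 + (it + 1) / adapt_interval))
            scales *= np.exp(step * (rate - target_acceptance))
            acc_window[:] = 0.0
        samples[it] = x
        lps[it] = cur_lp

    return ChainState(
        samples=samples,
        log_posterior=lps,
        accept_rate=acc_total / max(n_total, 1),
        scales=scales,
        seed=seed,
        n_adapt=n_adapt,
        blocks=blocks,
    )


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor R for one parameter.

    ``chains`` is an (m, n) array-like: m aligned chains of n post-burn-in
    samples each.  R is computed from the classic between/within variance
    decomposition; identical chains give sqrt((n-1)/n) <= 1, and zero
    within-chain variance with distinct chains is flagged as degenerate
    (R = inf).
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("at least two aligned chains are required")
    m, n = arr.shape
    if n < 10:
        raise ValueError("chains must have at least 10 samples")
    means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean()
    B_over_n = means.var(ddof=1)
    if W == 0.0:
        return np.inf  # degenerate: no within-chain variation
    var_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_hat / W))
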