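"""Latent propensity classes of recurrent copy-number alteration.

Across a cohort, each cytoband has some joint propensity for being deleted,
unmodified or amplified.  This module fits a mixture of nine trinomial
components over the per-band (loss, neutral, gain) sample counts; the nine
components are interpreted as a 3x3 grid of low/medium/high copy-loss level
by low/medium/high copy-gain level.  Bands are allocated to components by
the Bayes (maximum a posteriori) rule; the component with the highest loss
level and the lowest gain level defines the *exclusively deleted* bands and
its mirror image the *exclusively amplified* bands — bands whose aberration
is recurrently one-directional, suggesting a selective advantage of one
state with a disadvantage of the converse.

Components are fitted unconstrained and labeled afterwards: sorted into
loss-level terciles by their loss probability, then ordered by gain
probability within each tercile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .simulate import STATE_CNLOH, STATE_GAIN, STATE_LOSS, STATE_NEUTRAL

LEVELS = ("low", "medium", "high")

#: Reference 3x3 parameterization of the nine classes — joint probabilities
#: of (loss, neutral, gain) per (loss level, gain level) cell, typical of a
#: tumor cohort with more recurrent deletion than amplification.  Used as
#: the default ground truth of the cohort simulator.
REFERENCE_CLASS_PROBS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("low", "low"): (0.136, 0.839, 0.025),
    ("medium", "low"): (0.350, 0.631, 0.019),
    ("high", "low"): (0.693, 0.298, 0.009),
    ("low", "medium"): (0.121, 0.752, 0.127),
    ("medium", "medium"): (0.322, 0.580, 0.098),
    ("high", "medium"): (0.665, 0.286, 0.049),
    ("low", "high"): (0.102, 0.630, 0.268),
    ("medium", "high"): (0.280, 0.505, 0.215),
    ("high", "high"): (0.620, 0.266, 0.114),
}


def reference_class_probs() -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Reference class probabilities as an array plus (loss, gain) labels."""
    labels = list(REFERENCE_CLASS_PROBS)
    probs = np.array([REFERENCE_CLASS_PROBS[lab] for lab in labels])
    return probs / probs.sum(axis=1, keepdims=True), labels


@dataclass
class NineClassModel:
    pi: np.ndarray                      # (9,) mixing weights
    theta: np.ndarray                   # (9, 3) trinomial probabilities
    labels: list[tuple[str, str]]       # (loss_level, gain_level) per component
    loglik: float
    n_iter: int
    converged: bool

    def component(self, loss_level: str, gain_level: str) -> int:
        return self.labels.index((loss_level, gain_level))


@dataclass
class ExclusiveSets:
    deleted: set
    amplified: set


def counts_from_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-band loss/neutral/gain sample counts from a state matrix.

    CNLOH counts as Neutral (the propensity model describes loss/neutral/gain
    only); Missing entries are excluded, so band totals may fall below the
    cohort size; bands that are Missing in every sample are dropped with a
    warning.
    """
    loss = (matrix == STATE_LOSS).sum(axis=0)
    gain = (matrix == STATE_GAIN).sum(axis=0)
    neut = ((matrix == STATE_NEUTRAL) | (matrix == STATE_CNLOH)).sum(axis=0)
    counts = pd.DataFrame({"loss": loss, "neutral": neut, "gain": gain})
    empty = counts.sum(axis=1) == 0
    if empty.any():
        warnings.warn(f"dropping {int(empty.sum())} cytobands with no "
                      f"non-missing states")
        counts = counts[~empty]
    return counts


def _multinomial_loglik_matrix(x: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """(n_bands, k) log-likelihoods incl. the multinomial coefficient."""
    tot = x.sum(axis=1)
    const = gammaln(tot + 1) - gammaln(x + 1).sum(axis=1)
    return const[:, None] + x @ np.log(theta).T


def _label_components(theta: np.ndarray) -> list[tuple[str, str]]:
    """Assign the nine fitted components to the 3x3 loss-by-gain grid.

    The grid structure implies per-component loss and gain propensities
    a = lambda/(1-gamma) and c = gamma/(1-lambda) that take one of three
    values each (a per loss level, c per gain level).  Components are
    matched to cells by alternating between (i) estimating the three row
    and column propensities from the current assignment and (ii) solving
    the 9x9 linear assignment of components to cells under a squared
    propensity-distance cost.  This is robust where a plain tercile split
    of the loss probabilities misorders overlapping components.
    """
    from scipy.optimize import linear_sum_assignment

    lam = np.clip(theta[:, 0], 0.0, 1.0 - 1e-9)
    gam = np.clip(theta[:, 2], 0.0, 1.0 - 1e-9)
    a = lam / np.maximum(1.0 - gam, 1e-9)
    c = gam / np.maximum(1.0 - lam, 1e-9)
    row = np.empty(9, dtype=int)
    col = np.empty(9, dtype=int)
    row[np.argsort(a, kind="stable")] = np.repeat([0, 1, 2], 3)
    col[np.argsort(c, kind="stable")] = np.repeat([0, 1, 2], 3)
    for _ in range(50):
        a_bar = np.array([a[row == i].mean() for i in range(3)])
        c_bar = np.array([c[col == j].mean() for j in range(3)])
        # cost[k, 3*i + j] of placing component k in cell (loss i, gain j)
        cost = ((a[:, None] - a_bar[None, :])**2)[:, :, None] \
            + ((c[:, None] - c_bar[None, :])**2)[:, None, :]
        _, cell = linear_sum_assignment(cost.reshape(9, 9))
        new_row, new_col = cell // 3, cell % 3
        if (new_row == row).all() and (new_col == col).all():
            break
        row, col = new_row, new_col
    return [(LEVELS[i], LEVELS[j]) for i, j in zip(row, col)]


def fit_nine_class(counts, n_starts: int = 20, seed: int = 0, tol: float = 1e-8,
                   max_iter: int = 2000) -> NineClassModel:
    """EM fit of the 9-component trinomial mixture over band counts.

    Runs ``n_starts`` random initializations (Dirichlet-drawn component
    probabilities) and keeps the best log-likelihood.  The log-likelihood is
    non-decreasing within each run; non-convergence after ``max_iter`` keeps
    the best iterate with ``converged=False``.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("counts must be (n_bands, 3)")
    if x.shape[0] < 9:
        raise ValueError("need at least 9 cytobands to fit 9 classes")
    k = 9
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(n_starts, 1)):
        theta = rng.dirichlet(np.ones(3), size=k)
        pi = np.full(k, 1.0 / k)
        prev = -np.inf
        conv = False
        it = 0
        for it in range(1, max_iter + 1):
            ll = _multinomial_loglik_matrix(x, np.clip(theta, 1e-12, 1.0))
            joint = ll + np.log(np.clip(pi, 1e-12, 1.0))
            norm = logsumexp(joint, axis=1)
            loglik = float(norm.sum())
            resp = np.exp(joint - norm[:, None])
            pi = resp.mean(axis=0)
            wx = resp.T @ x + 1e-10
            theta = wx / wx.sum(axis=1, keepdims=True)
            if loglik - prev < tol * (abs(prev) + 1.0) and it > 1:
                conv = True
                prev = loglik
                break
            prev = loglik
        if best is None or prev > best[0]:
            best = (prev, pi.copy(), theta.copy(), it, conv)
    loglik, pi, theta, n_iter, converged = best
    if not converged:
        warnings.warn("EM did not converge; returning best iterate")
    return NineClassModel(pi=pi, theta=theta, labels=_label_components(theta),
                          loglik=loglik, n_iter=n_iter, converged=converged)


def allocate_bayes(model: NineClassModel, counts) -> tuple[np.ndarray, np.ndarray]:
    """MAP component per band and the (n_bands, 9) posterior matrix.

    Posterior rows sum to one; exact ties resolve to the lowest component
    index.
    """
    x = np.asarray(counts, dtype=float)
    joint = _multinomial_loglik_matrix(x, np.clip(model.theta, 1e-12, 1.0)) \
        + np.log(np.clip(model.pi, 1e-12, 1.0))
    post = np.exp(joint - logsumexp(joint, axis=1)[:, None])
    return np.argmax(post, axis=1), post


def select_exclusive(model: NineClassModel, allocations: np.ndarray,
                     band_names=None) -> ExclusiveSets:
    """Bands in the (loss=high, gain=low) / (loss=low, gain=high) components."""
    alloc = np.asarray(allocations)
    names = np.arange(alloc.size) if band_names is None else np.asarray(band_names)
    deleted = set(names[alloc == model.component("high", "low")])
    amplified = set(names[alloc == model.component("low", "high")])
    return ExclusiveSets(deleted=deleted, amplified=amplified)


def collapse_states(matrix: pd.DataFrame, exclusive: ExclusiveSets) -> pd.DataFrame:
    """Merge contradictory rare states into Neutral on exclusive bands.

    On exclusively amplified bands the few losses become Neutral and the
    converse on exclusively deleted bands; everything else is unchanged.
    """
    out = matrix.copy()
    amp = [b for b in out.columns if b in exclusive.amplified]
    dele = [b for b in out.columns if b in exclusive.deleted]
    out[amp] = out[amp].replace(STATE_LOSS, STATE_NEUTRAL)
    out[dele] = out[dele].replace(STATE_GAIN, STATE_NEUTRAL)
    return out


def component_table(model: NineClassModel) -> pd.DataFrame:
    """3x3-grid component summary (weights and cell probabilities)."""
    rows = []
    for k, (loss_level, gain_level) in enumerate(model.labels):
        rows.append({
            "loss_level": loss_level, "gain_level": gain_level,
            "weight": model.pi[k], "p_loss": model.theta[k, 0],
            "p_neutral": model.theta[k, 1], "p_gain": model.theta[k, 2],
        })
    return pd.DataFrame(rows).sort_values(["gain_level", "loss_level"]) \
        .reset_index(drop=True)
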