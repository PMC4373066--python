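"""Model-based clustering of tumors over exclusive-cytoband states.

Samples are clustered on their categorical {Loss, Neutral, Gain} states over
the exclusively deleted/amplified cytobands with a latent-class model in
which *relevant* bands have cluster-specific multinomials while *irrelevant*
bands share one multinomial across clusters.  The number of clusters K and
the relevant subset are chosen jointly by BIC (2*loglik - nu*log S, larger
is better) with a greedy backward stepwise search over bands inside a sweep
over K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .simulate import STATE_CNLOH, STATE_GAIN, STATE_LOSS, STATE_NEUTRAL

_STATE_CODE = {STATE_LOSS: 0, STATE_NEUTRAL: 1, STATE_CNLOH: 1, STATE_GAIN: 2}
N_STATES = 3


def encode_states(matrix: pd.DataFrame) -> np.ndarray:
    """Samples x bands integer codes (Loss 0, Neutral/CNLOH 1, Gain 2)."""
    values = matrix.to_numpy(dtype=object)
    codes = np.empty(values.shape, dtype=int)
    for state, code in _STATE_CODE.items():
        codes[values == state] = code
    known = np.isin(values, list(_STATE_CODE))
    if not known.all():
        bad = sorted({str(v) for v in values[~known]})
        raise ValueError(f"state matrix must contain only "
                         f"Loss/Neutral/Gain/CNLOH; found {bad}")
    return codes


@dataclass
class LCAModel:
    n_clusters: int
    tau: np.ndarray                # (K,) cluster weights
    theta: np.ndarray              # (K, p, 3) cluster-specific multinomials
    shared: np.ndarray             # (p, 3) shared multinomial
    relevant: np.ndarray           # (p,) boolean mask
    loglik: float
    bic: float
    n_params: int
    converged: bool
    posterior: np.ndarray          # (S, K)

    @property
    def assignments(self) -> np.ndarray:
        return np.argmax(self.posterior, axis=1)


@dataclass
class ClusteringResult:
    n_clusters: int
    relevant_bands: list
    assignments: np.ndarray
    posterior: np.ndarray
    model: LCAModel
    bic_by_k: dict[int, float]
    visited_bics: list[float]


def _one_hot(codes: np.ndarray) -> np.ndarray:
    s, p = codes.shape
    hot = np.zeros((s, p, N_STATES))
    ii, jj = np.meshgrid(np.arange(s), np.arange(p), indexing="ij")
    hot[ii, jj, codes] = 1.0
    return hot


def _shared_loglik(hot: np.ndarray, cols: np.ndarray) -> tuple[float, np.ndarray]:
    """Saturated-by-column multinomial log-likelihood of the given bands."""
    if not cols.any():
        return 0.0, np.zeros((0, N_STATES))
    counts = hot[:, cols, :].sum(axis=0)
    probs = (counts + 1e-10) / (counts + 1e-10).sum(axis=1, keepdims=True)
    ll = float((counts * np.log(probs)).sum())
    return ll, probs


def fit_lca(states, n_clusters: int, relevant=None, n_starts: int = 10,
            seed: int = 0, tol: float = 1e-8, max_iter: int = 500,
            init_resp: np.ndarray | None = None) -> LCAModel:
    """EM fit of the latent-class model at fixed K and relevant set.

    ``states`` is a samples x bands matrix of state labels or integer codes.
    Irrelevant bands contribute a closed-form shared-multinomial term that
    factors out of the mixture.  Restarts on empty clusters; if every start
    degenerates the best fit is returned with ``converged=False``.
    ``init_resp`` warm-starts a single EM run from given responsibilities.
    """
    codes = states if isinstance(states, np.ndarray) else encode_states(states)
    s, p = codes.shape
    k = int(n_clusters)
    if k < 1 or s <= k:
        raise ValueError("need 1 <= K < n_samples")
    rel = np.ones(p, bool) if relevant is None else np.asarray(relevant, bool)
    hot = _one_hot(codes)
    ll_shared, shared_probs = _shared_loglik(hot, ~rel)
    shared_full = np.zeros((p, N_STATES))
    if (~rel).any():
        shared_full[~rel] = shared_probs
    hot_rel = hot[:, rel, :]
    n_rel = int(rel.sum())

    if k == 1 or n_rel == 0:
        ll_rel, rel_probs = _shared_loglik(hot, rel)
        theta = np.zeros((k, p, N_STATES))
        theta[:, rel, :] = rel_probs
        loglik = ll_rel + ll_shared
        n_params = (k - 1) + (N_STATES - 1) * (k * n_rel + (p - n_rel))
        return LCAModel(k, np.ones(k) / k, theta, shared_full, rel, loglik,
                        2 * loglik - n_params * np.log(s), n_params, True,
                        np.ones((s, k)) / k)

    rng = np.random.default_rng(seed)
    best = None
    starts = 1 if init_resp is not None else max(n_starts, 1)
    for start in range(starts):
        if init_resp is not None:
            resp = init_resp
        else:
            # seed clusters with K random samples; soft-assign the rest by
            # Hamming distance over the relevant bands
            seeds = rng.choice(s, size=k, replace=False)
            dist = (codes[:, rel][:, None, :] != codes[seeds][None, :, rel]).sum(axis=2)
            resp = np.exp(-dist.astype(float))
            resp += rng.random(resp.shape) * 0.05 + 1e-3
            resp /= resp.sum(axis=1, keepdims=True)
        prev = -np.inf
        conv = False
        degenerate = False
        for _ in range(max_iter):
            tau = resp.mean(axis=0)
            if tau.min() < 1.0 / (10.0 * s):
                degenerate = True
                break
            cnt = np.einsum("sk,spc->kpc", resp, hot_rel) + 1e-10
            theta_rel = cnt / cnt.sum(axis=2, keepdims=True)
            logl = np.einsum("spc,kpc->sk", hot_rel, np.log(theta_rel))
            joint = logl + np.log(tau)
            norm = logsumexp(joint, axis=1)
            loglik = float(norm.sum())
            resp = np.exp(joint - norm[:, None])
            if loglik - prev < tol * (abs(prev) + 1.0) and prev > -np.inf:
                conv = True
                prev = loglik
                break
            prev = loglik
        if degenerate and init_resp is None:
            continue
        total = prev + ll_shared
        if best is None or total > best[0]:
            theta = np.zeros((k, p, N_STATES))
            theta[:, rel, :] = theta_rel
            best = (total, tau.copy(), theta, resp.copy(), conv)
    if best is None:  # every start collapsed a cluster
        ll_rel, rel_probs = _shared_loglik(hot, rel)
        theta = np.zeros((k, p, N_STATES))
        theta[:, rel, :] = rel_probs
        loglik = ll_rel + ll_shared
        n_params = (k - 1) + (N_STATES - 1) * (k * n_rel + (p - n_rel))
        return LCAModel(k, np.ones(k) / k, theta, shared_full, rel, loglik,
                        2 * loglik - n_params * np.log(s), n_params, False,
                        np.ones((s, k)) / k)
    loglik, tau, theta, resp, conv = best
    n_params = (k - 1) + (N_STATES - 1) * (k * n_rel + (p - n_rel))
    return LCAModel(k, tau, theta, shared_full, rel, loglik,
                    2 * loglik - n_params * np.log(s), n_params, conv, resp)


def _backward_select(codes: np.ndarray, k: int, n_starts: int, seed: int,
                     visited: list[float]) -> LCAModel:
    """Greedy backward stepwise removal of bands from the relevant set.

    Candidates are tried in order of their per-band evidence for
    cluster-specific behaviour (expected complete-data log-likelihood gain at
    the current posteriors); a move is kept only if the exactly refitted BIC
    improves.  Terminates when no single removal improves BIC.
    """
    s, p = codes.shape
    hot = _one_hot(codes)
    rel = np.ones(p, bool)
    model = fit_lca(codes, k, rel, n_starts=n_starts, seed=seed)
    visited.append(model.bic)
    if k == 1:
        return model
    for refresh in range(1, 25):
        improved = True
        while improved and rel.sum() > 1:
            improved = False
            resp = model.posterior
            cnt = np.einsum("sk,spc->kpc", resp, hot) + 1e-10
            th = cnt / cnt.sum(axis=2, keepdims=True)
            q_rel = np.einsum("kpc,kpc->p", cnt, np.log(th))
            cnt_sh = hot.sum(axis=0) + 1e-10
            th_sh = cnt_sh / cnt_sh.sum(axis=1, keepdims=True)
            q_irr = np.einsum("pc,pc->p", cnt_sh, np.log(th_sh))
            # expected BIC gain of moving band j out of the relevant set
            gain = 2.0 * (q_irr - q_rel) + (N_STATES - 1) * (k - 1) * np.log(s)
            order = np.argsort(-gain)
            for j in order:
                if not rel[j] or rel.sum() <= 1:
                    continue
                trial = rel.copy()
                trial[j] = False
                cand = fit_lca(codes, k, trial, seed=seed,
                               init_resp=model.posterior)
                visited.append(cand.bic)
                if cand.bic > model.bic:
                    rel = trial
                    model = cand
                    improved = True
                elif gain[j] <= 0:
                    break  # remaining candidates are even less promising
        # warm-started pruning can lock in one partition; a fresh multi-start
        # fit on the pruned set may find a better one, in which case the
        # pruning sweep is resumed from it
        fresh = fit_lca(codes, k, rel, n_starts=n_starts, seed=seed + refresh)
        visited.append(fresh.bic)
        if fresh.bic > model.bic + 1e-9:
            model = fresh
        else:
            break
    return model


def select_model(states, k_range=range(1, 7), seed: int = 0,
                 n_starts: int = 20) -> ClusteringResult:
    """Joint choice of cluster count and relevant bands by BIC.

    For each K in ``k_range`` the relevant set is pruned by greedy backward
    stepwise search; the (K, relevant set) pair with the best BIC wins.
    """
    if isinstance(states, pd.DataFrame):
        codes = encode_states(states)
        names = np.asarray(states.columns)
    else:
        codes = np.asarray(states, dtype=int)
        names = np.arange(codes.shape[1])
    visited: list[float] = []
    bic_by_k: dict[int, float] = {}
    best: LCAModel | None = None
    for k in k_range:
        if k >= codes.shape[0]:
            continue
        model = _backward_select(codes, k, n_starts, seed + 17 * k, visited)
        bic_by_k[k] = model.bic
        if best is None or model.bic > best.bic:
            best = model
    if best is None:
        raise ValueError("no admissible K in k_range")
    return ClusteringResult(
        n_clusters=best.n_clusters,
        relevant_bands=list(names[best.relevant]),
        assignments=best.assignments,
        posterior=best.posterior,
        model=best,
        bic_by_k=bic_by_k,
        visited_bics=visited,
    )


def write_assignments(result: ClusteringResult, sample_names, path) -> None:
    """Tab-separated table: sample, cluster, max posterior probability."""
    with open(path, "w") as fh:
        fh.write("sample\tcluster\tposterior_max\n")
        for name, g, post in zip(sample_names, result.assignments,
                                 result.posterior.max(axis=1)):
            fh.write(f"{name}\t{g + 1}\t{post:.4f}\n")
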