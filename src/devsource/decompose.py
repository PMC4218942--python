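"""Full-rank ICA of the continuous retained data.

The engine is extended Infomax: natural-gradient maximum-likelihood ICA
with per-component sub-/super-Gaussian switching, run on symmetrically
sphered data.  Two study-specific behaviours wrap the engine:

* a sample-rejection schedule — after selected early passes (default
  4, 7, 10, 13, 16) samples whose model log-likelihood falls more than
  5 SD below the mean are excluded from all subsequent updates;
* a convergence trace carrying the data log-likelihood and the
  mutual-information-reduction (MIR) diagnostic, whose asymptote is the
  practical convergence criterion for the decomposition.

Scale/sign indeterminacy is resolved by unit-norm scalp maps with the
largest-magnitude channel positive; components are ordered by
descending mean back-projected variance.  The engine is pluggable in
principle (anything returning an unmixing matrix can slot in); the
schedule and diagnostics are engine-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .data_io import Recording, ValidationError

__all__ = [
    "ICADecomposition",
    "run_ica",
    "mutual_information_reduction",
    "ic_spectrum",
    "amari_index",
]


@dataclass
class ICADecomposition:
    """Result of one ICA run.

    ``unmixing`` maps channel data (µV, mean-removed) to activations:
    ``activations = unmixing @ data``; ``mixing`` is its pseudo-inverse,
    whose unit-norm columns are the IC scalp maps.
    """

    unmixing: np.ndarray  # components × channels (includes sphering)
    mixing: np.ndarray  # channels × components
    channel_names: list[str]
    mean: np.ndarray  # channel means removed before decomposition
    sample_reject_mask: np.ndarray  # True where samples were excluded
    trace: list[dict] = field(default_factory=list)
    n_components: int = 0

    def __post_init__(self) -> None:
        self.n_components = self.unmixing.shape[0]

    @property
    def scalp_maps(self) -> np.ndarray:
        """(channels × components); columns are unit-norm."""
        return self.mixing

    def activations(self, rec: Recording, retained_only: bool = False) -> np.ndarray:
        data = rec.data[:, rec.retained_mask] if retained_only else rec.data
        return self.unmixing @ (data - self.mean[:, None])


def _loglik(u: np.ndarray, signs: np.ndarray, logdet: float) -> np.ndarray:
    """Per-sample model log-likelihood under the extended-Infomax prior.

    Super-Gaussian components (sign +1) use the logistic-like density
    log p(u) ∝ -u²/2 - 2 log cosh u; sub-Gaussian (sign -1) use the
    symmetric bimodal Pearson mixture surrogate -u²/2 + log cosh u.
    Constants are dropped — only relative values feed the SD rule.
    """
    per = -0.5 * u**2 - (2.0 * signs[:, None]) * np.logaddexp(u, -u)
    return per.sum(axis=0) + logdet


def run_ica(
    rec: Recording,
    n_components: int | None = None,
    max_iter: int = 2000,
    reject_sd: float = 5.0,
    reject_iters: tuple[int, ...] = (4, 7, 10, 13, 16),
    seed: int = 0,
    tol: float = 1e-7,
    lrate: float | None = None,
    trace_every: int = 10,
) -> ICADecomposition:
    """Decompose the retained portion of a recording by extended Infomax.

    One iteration is one randomized pass over the (currently retained)
    sphered data in blocks.  Stops at ``max_iter`` or when the weight
    change drops below ``tol``.  Rank-deficient data are projected onto
    their principal subspace first (recorded in the trace).
    """
    if not np.all(np.isfinite(rec.data)):
        raise ValidationError("recording contains non-finite samples")
    x = rec.data[:, rec.retained_mask]
    n_ch, n_samp = x.shape
    if n_samp < 5 * n_ch**2:
        raise ValidationError(
            f"{n_samp} samples is too few for a {n_ch}-channel decomposition"
        )
    import warnings as _w

    if n_samp < 20 * n_ch**2:
        _w.warn("fewer than 20·channels² samples; decomposition may be unstable")

    mean = x.mean(axis=1)
    xc = x - mean[:, None]

    # symmetric sphering, with principal-subspace projection if rank deficient
    cov = (xc @ xc.T) / n_samp
    evals, evecs = np.linalg.eigh(cov)
    good = evals > max(evals.max() * 1e-10, 0.0)
    rank = int(good.sum())
    subspace_note = None
    if n_components is None:
        n_components = rank if rank < n_ch else n_ch
    if rank < n_ch or n_components < n_ch:
        k = min(rank, n_components)
        sel = evecs[:, -k:]
        lam = evals[-k:]
        sphere = (sel / np.sqrt(lam)).T  # k × channels
        subspace_note = f"projected {n_ch} channels onto {k}-D principal subspace"
    else:
        k = n_ch
        sphere = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T
    xw = sphere @ xc  # k × samples
    k_comp = xw.shape[0]

    rng = np.random.default_rng(seed)
    W = np.eye(k_comp)
    lr = lrate if lrate is not None else 0.002
    block = int(np.clip(np.floor(np.sqrt(n_samp / 3.0)), 8, 512))
    signs = np.ones(k_comp)  # +1 super-Gaussian, -1 sub-Gaussian
    eye = np.eye(k_comp)

    active = np.ones(n_samp, dtype=bool)
    trace: list[dict] = []
    if subspace_note:
        trace.append({"note": subspace_note})

    W_old = W.copy()
    prev_delta: np.ndarray | None = None
    anneal_deg_cos = np.cos(np.deg2rad(60.0))
    for it in range(1, max_iter + 1):
        idx = rng.permutation(np.flatnonzero(active))
        for start in range(0, idx.size - block + 1, block):
            sel = idx[start : start + block]
            u = W @ xw[:, sel]
            y = np.tanh(u)
            grad = (block * eye - (signs[:, None] * y) @ u.T - u @ u.T) @ W
            W = W + (lr / block) * grad
            if not np.all(np.isfinite(W)):  # diverged: restart colder
                W = W_old.copy()
                lr *= 0.5
                break
        # sub/super-Gaussian switching from the sign of a kurtosis estimate
        sub = xw[:, idx[: min(idx.size, 4096)]]
        us = W @ sub
        kurt = (us**4).mean(axis=1) - 3.0 * (us**2).mean(axis=1) ** 2
        signs = np.where(kurt >= 0, 1.0, -1.0)

        delta = np.linalg.norm(W - W_old) / max(np.linalg.norm(W_old), 1e-30)
        # anneal when successive pass updates change direction sharply
        # (oscillation near the optimum), after the rejection schedule
        dW = (W - W_old).ravel()
        if prev_delta is not None and it > max(reject_iters, default=0):
            denom = np.linalg.norm(dW) * np.linalg.norm(prev_delta)
            if denom > 0 and (dW @ prev_delta) / denom < anneal_deg_cos:
                lr = max(lr * 0.9, 1e-6)
        prev_delta = dW
        W_old = W.copy()

        do_reject = it in reject_iters
        if do_reject or it % trace_every == 0 or it == 1:
            u_all = W @ xw[:, active]
            logdet = float(np.linalg.slogdet(W)[1])
            ll = _loglik(u_all, signs, logdet)
            entry = {
                "iteration": it,
                "objective": float(ll.mean()),
                "weight_change": float(delta),
                "n_active": int(active.sum()),
            }
            if do_reject:
                cut = ll.mean() - reject_sd * ll.std()
                bad = ll < cut
                active_idx = np.flatnonzero(active)
                active[active_idx[bad]] = False
                entry["n_rejected_now"] = int(bad.sum())
            entry["mir_bits"] = _mir_bits(xc[:, active], W @ sphere)
            trace.append(entry)
        if delta < tol and it > max(reject_iters, default=0):
            trace.append({"iteration": it, "converged": True, "weight_change": float(delta)})
            break

    unmixing = W @ sphere  # components × channels
    mixing = np.linalg.pinv(unmixing)

    # resolve scale/sign/order: unit-norm maps, dominant channel positive,
    # order by descending back-projected variance
    norms = np.linalg.norm(mixing, axis=0)
    norms[norms == 0] = 1.0
    mixing = mixing / norms[None, :]
    unmixing = unmixing * norms[:, None]
    dom = np.argmax(np.abs(mixing), axis=0)
    flip = np.sign(mixing[dom, np.arange(k_comp)])
    flip[flip == 0] = 1.0
    mixing *= flip[None, :]
    unmixing *= flip[:, None]
    act_var = (unmixing @ xc).var(axis=1)  # map is unit-norm: projected variance
    order = np.argsort(-act_var, kind="stable")
    # deterministic tie-break by first-channel map value
    order = order[np.lexsort((-mixing[0, order], np.round(-act_var[order], 12)))]
    mixing = mixing[:, order]
    unmixing = unmixing[order]

    reject_mask = np.zeros(rec.n_samples, dtype=bool)
    retained_idx = np.flatnonzero(rec.retained_mask)
    reject_mask[retained_idx[~active]] = True

    return ICADecomposition(
        unmixing=unmixing,
        mixing=mixing,
        channel_names=list(rec.channel_names),
        mean=mean,
        sample_reject_mask=reject_mask,
        trace=trace,
    )


def _hist_entropy_bits(x: np.ndarray, n_bins: int = 512) -> float:
    """Differential entropy (bits) by histogram over ±5 SD."""
    sd = x.std()
    if sd == 0:
        return 0.0
    lo, hi = x.mean() - 5 * sd, x.mean() + 5 * sd
    hist, edges = np.histogram(np.clip(x, lo, hi), bins=n_bins, range=(lo, hi))
    p = hist / hist.sum()
    w = edges[1] - edges[0]
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum() + np.log2(w))


def _mir_bits(xc: np.ndarray, unmixing: np.ndarray) -> float:
    u = unmixing @ xc
    h_x = sum(_hist_entropy_bits(xc[i]) for i in range(xc.shape[0]))
    h_u = sum(_hist_entropy_bits(u[i]) for i in range(u.shape[0]))
    sign, logdet = np.linalg.slogdet(unmixing @ unmixing.T)
    return float(h_x - h_u + 0.5 * logdet / np.log(2.0))


def mutual_information_reduction(
    rec: Recording, decomp: ICADecomposition
) -> float:
    """MIR (bits) of the channels→ICs transform on the retained data.

    MIR = Σ h(xᵢ) − Σ h(uᵢ) + log|det W|, marginal entropies estimated
    by 512-bin histograms; the identity transform gives exactly 0.
    """
    xc = rec.data[:, rec.retained_mask] - decomp.mean[:, None]
    return _mir_bits(xc, decomp.unmixing)


def ic_spectrum(
    decomp: ICADecomposition,
    rec: Recording,
    lo_hz: float = 3.0,
    hi_hz: float = 50.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-IC mean log power spectrum, scalp-projected units.

    Welch (2-s Hann windows, 50 % overlap) on each activation scaled by
    its map's largest-|value| channel gain; returns ``(freqs, 10·log10
    power)`` restricted to [lo_hz, hi_hz].
    """
    acts = decomp.activations(rec, retained_only=True)
    gains = np.abs(decomp.mixing).max(axis=0)
    nper = int(2 * rec.fs)
    nper = min(nper, acts.shape[1])
    f, pxx = sps.welch(
        acts * gains[:, None], fs=rec.fs, window="hann", nperseg=nper,
        noverlap=nper // 2, axis=1,
    )
    sel = (f >= lo_hz) & (f <= hi_hz)
    return f[sel], 10.0 * np.log10(np.maximum(pxx[:, sel], 1e-300))


def amari_index(estimated_unmixing: np.ndarray, true_mixing: np.ndarray) -> float:
    """Permutation/scale-invariant recovery error; 0 = perfect unmixing.

    For P = W·A the index averages how far each row and column of |P|
    is from having a single dominant entry, normalised to [0, 1].
    """
    P = np.abs(np.asarray(estimated_unmixing) @ np.asarray(true_mixing))
    n = P.shape[0]
    row = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    col = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((row.sum() + col.sum()) / (2.0 * n * (n - 1)))
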