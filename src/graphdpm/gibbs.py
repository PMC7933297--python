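"""Blocked Gibbs sampler for the graph-guided DPM — a small-scale oracle.

Samples the same truncated stick-breaking posterior targeted by the
variational engine, by drawing each block from its full conditional:

* z_i   ~ categorical over h, proportional to w'_h times the product of
          active/null densities at the current (gamma, theta);
* w_h   ~ Beta(1 + n_h, alpha0 + n_{>h}) for h < H (w_H = 1);
* (gamma_jh, theta_jh) as one block: gamma_jh ~ Bernoulli with log-odds =
          marginal-likelihood difference (active parameters integrated out
          under the conjugate base measure) over the subjects of cluster h,
          plus the Ising conditional from current neighbor indicators; then
* (mu_jh, sigma2_jh) ~ Normal-Inverse-Gamma posterior over the subjects with
          z_i = h when gamma_jh = 1, the base measure otherwise, and
          p_jh ~ Beta posterior likewise.

Sampling gamma against the *integrated* likelihood (rather than a sampled
theta) is what lets selection indicators flip: a fresh base-measure draw of
theta essentially never matches the data, which would freeze gamma at 0.

This is an independent reference implementation of the posterior, intended
for tiny instances; it shares the truncation structure with the VB engine so
their point partitions are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, expit, gammaln

from .data import ModalityKind, MultiModalDataset, NullParams, log_density_null
from .graphs import GraphSet
from .vb import Hyperparameters, stick_weights

__all__ = ["GibbsConfig", "GibbsDraws", "gibbs_fit", "posterior_similarity"]

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class GibbsConfig:
    iters: int = 2000
    burnin: int = 1000
    thin: int = 2
    seed: int = 0
    init: str = "kmeans"  # affects mixing only, not the stationary distribution

    def __post_init__(self) -> None:
        if not self.iters > self.burnin >= 0:
            raise ValueError("need iters > burnin >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class GibbsDraws:
    z: list[np.ndarray] = field(default_factory=list)  # each (n,), 1-based labels
    w: list[np.ndarray] = field(default_factory=list)  # each (H,) raw sticks
    gamma: list[list[np.ndarray]] = field(default_factory=list)  # per modality (p_m, H)
    normal: list[dict[int, tuple[np.ndarray, np.ndarray]]] = field(default_factory=list)
    bern: list[dict[int, np.ndarray]] = field(default_factory=list)
    n_sweeps: int = 0  # total Gibbs sweeps performed (audit)

    @property
    def n_retained(self) -> int:
        return len(self.z)


def gibbs_fit(
    data: MultiModalDataset,
    graphs: GraphSet | None,
    hyper: Hyperparameters,
    config: GibbsConfig = GibbsConfig(),
    *,
    force: bool = False,
) -> GibbsDraws:
    """Run the blocked sampler and return retained draws.

    Guard: refuses instances with n * p * H > 1e7 unless ``force=True`` —
    the sampler is a correctness oracle, not a production engine.
    Deterministic given ``config.seed``.
    """
    n, p, H = data.n_samples, data.n_features, hyper.H
    if n * p * H > 1e7 and not force:
        raise ValueError(
            f"instance size n*p*H = {n * p * H:.3g} exceeds the oracle guard (1e7); "
            "pass force=True to override"
        )
    if graphs is None:
        graphs = GraphSet(n_modalities=len(data.modalities))
    rng = np.random.default_rng(config.seed)
    null = NullParams()
    M = len(data.modalities)
    eta, nu, nu_c = hyper.ising.eta, hyper.ising.nu, hyper.ising.nu_cross
    if len(eta) != M:
        if len(eta) == 1:
            eta, nu = eta * M, nu * M
        else:
            raise ValueError("ising hyperparameters must supply one eta/nu per modality")
    adj = graphs.adjacency()

    ln_null = [np.asarray(log_density_null(X, spec.kind, null)) for spec, X in data.modalities]

    # --- init
    if config.init == "kmeans":
        from sklearn.cluster import KMeans

        Xcat = np.hstack([X for _, X in data.modalities])
        mu_ = Xcat.mean(axis=0)
        sd = Xcat.std(axis=0)
        sd[sd == 0] = 1.0
        k = min(H, n)
        z = KMeans(n_clusters=k, n_init=5, random_state=config.seed).fit_predict(
            (Xcat - mu_) / sd
        )
    else:
        z = rng.integers(0, H, size=n)
    w = np.ones(H)
    if H > 1:
        w[: H - 1] = rng.beta(1.0, hyper.alpha0, size=H - 1)
    gamma = [rng.integers(0, 2, size=(spec.n_features, H)) for spec, _ in data.modalities]
    theta_n: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    theta_b: dict[int, np.ndarray] = {}
    for mi, (spec, _) in enumerate(data.modalities):
        p_m = spec.n_features
        if spec.kind is ModalityKind.NORMAL:
            sig2 = 1.0 / rng.gamma(hyper.alpha_sigma, 1.0 / hyper.beta_sigma, size=(p_m, H))
            mu = rng.normal(0.0, np.sqrt(sig2 / hyper.lam))
            theta_n[mi] = (mu, sig2)
        else:
            theta_b[mi] = rng.beta(hyper.alpha_p, hyper.beta_p, size=(p_m, H))

    draws = GibbsDraws()
    onehot = np.zeros((n, H))

    for sweep in range(config.iters):
        onehot[:] = 0.0
        onehot[np.arange(n), z] = 1.0
        counts = onehot.sum(axis=0)

        # --- gamma | z (active parameters integrated out) --------------------
        # collapsed log-odds: log marginal lik (conjugate) minus null loglik
        dlik = []
        suff = {}
        for mi, (spec, X) in enumerate(data.modalities):
            S1 = X.T @ onehot  # (p_m, H)
            if spec.kind is ModalityKind.NORMAL:
                S2 = (X**2).T @ onehot
                suff[mi] = (S1, S2)
                v = hyper.lam + counts[None, :]
                m_ = S1 / v
                aN = hyper.alpha_sigma + counts[None, :] / 2.0
                bN = hyper.beta_sigma + 0.5 * np.maximum(S2 - v * m_**2, 0.0)
                log_ml = (
                    -0.5 * counts[None, :] * np.log(2.0 * np.pi)
                    + 0.5 * (np.log(hyper.lam) - np.log(v))
                    + hyper.alpha_sigma * np.log(hyper.beta_sigma)
                    - gammaln(hyper.alpha_sigma)
                    + gammaln(aN)
                    - aN * np.log(bN)
                )
            else:
                suff[mi] = (S1, None)
                log_ml = (
                    betaln(hyper.alpha_p + S1, hyper.beta_p + counts[None, :] - S1)
                    - betaln(hyper.alpha_p, hyper.beta_p)
                )
            dlik.append(log_ml - ln_null[mi].T @ onehot)
        for mi, (spec, _) in enumerate(data.modalities):
            p_m = spec.n_features
            base_all = dlik[mi] - eta[mi]
            free = [j for j in range(p_m) if (mi, j) not in adj]
            if free:
                gamma[mi][free] = rng.random((len(free), H)) < expit(base_all[free])
            for j in range(p_m):
                if (mi, j) not in adj:
                    continue
                fieldv = np.zeros(H)
                for gm, k, tag in adj[(mi, j)]:
                    strength = nu[mi] if tag == "within" else nu_c
                    fieldv += strength * (2.0 * gamma[gm][k] - 1.0)
                gamma[mi][j] = rng.random(H) < expit(base_all[j] + fieldv)

        # --- theta | z, gamma ------------------------------------------------
        for mi, (spec, X) in enumerate(data.modalities):
            S1, S2 = suff[mi]
            g_ = gamma[mi]
            if spec.kind is ModalityKind.NORMAL:
                W = g_ * counts[None, :]
                v = hyper.lam + W
                m_ = (g_ * S1) / v
                d = 2.0 * hyper.alpha_sigma + W
                r = 2.0 * hyper.beta_sigma + g_ * S2 - v * m_**2
                r = np.maximum(r, 2.0 * hyper.beta_sigma * 1e-10)
                sig2 = r / (2.0 * rng.gamma(d / 2.0, 1.0))
                mu = m_ + rng.standard_normal(size=m_.shape) * np.sqrt(sig2 / v)
                theta_n[mi] = (mu, sig2)
            else:
                s = hyper.alpha_p + g_ * S1
                t = hyper.beta_p + g_ * (counts[None, :] - S1)
                theta_b[mi] = np.clip(rng.beta(s, t), 1e-9, 1.0 - 1e-9)

        # --- z | w, gamma, theta --------------------------------------------
        wp = stick_weights(w)
        logp = np.log(np.maximum(wp, 1e-300))[None, :].repeat(n, axis=0)
        for mi, (spec, X) in enumerate(data.modalities):
            g_ = gamma[mi].astype(float)
            logp += ln_null[mi].sum(axis=1, keepdims=True) - ln_null[mi] @ g_
            if spec.kind is ModalityKind.NORMAL:
                mu, sig2 = theta_n[mi]
                const = -_HALF_LOG_2PI - 0.5 * np.log(sig2)
                a = g_ / sig2
                logp += (g_ * (const - 0.5 * mu**2 / sig2)).sum(axis=0)
                logp += X @ (a * mu) - 0.5 * (X**2) @ a
            else:
                pr = theta_b[mi]
                logp += X @ (g_ * np.log(pr)) + (1.0 - X) @ (g_ * np.log1p(-pr))
        logp -= logp.max(axis=1, keepdims=True)
        prob = np.exp(logp)
        prob /= prob.sum(axis=1, keepdims=True)
        u = rng.random((n, 1))
        z = (prob.cumsum(axis=1) < u).sum(axis=1)

        # --- w | z -----------------------------------------------------------
        cnt = np.bincount(z, minlength=H).astype(float)
        tail = np.concatenate([np.cumsum(cnt[::-1])[::-1][1:], [0.0]])
        if H > 1:
            w[: H - 1] = rng.beta(1.0 + cnt[: H - 1], hyper.alpha0 + tail[: H - 1])
        w[H - 1] = 1.0

        if sweep >= config.burnin and (sweep - config.burnin) % config.thin == 0:
            draws.z.append(z.copy() + 1)
            draws.w.append(w.copy())
            draws.gamma.append([g.copy() for g in gamma])
            draws.normal.append({mi: (t[0].copy(), t[1].copy()) for mi, t in theta_n.items()})
            draws.bern.append({mi: t.copy() for mi, t in theta_b.items()})
    draws.n_sweeps = config.iters
    return draws


def posterior_similarity(draws: GibbsDraws) -> tuple[np.ndarray, np.ndarray]:
    """Co-clustering probability matrix and a point partition.

    Entry (i, k) is the fraction of retained draws in which subjects i and k
    share a cluster.  The point partition is the retained draw whose Rand
    index against the thresholded-similarity partition (edges at > 0.5,
    connected components) is highest; ties resolve to the earliest draw.
    """
    if draws.n_retained < 1:
        raise ValueError("need at least one retained draw")
    n = draws.z[0].shape[0]
    sim = np.zeros((n, n))
    for z in draws.z:
        sim += (z[:, None] == z[None, :]).astype(float)
    sim /= draws.n_retained

    # connected components of the >0.5 co-clustering graph (union-find)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for k in range(i + 1, n):
            if sim[i, k] > 0.5:
                ra, rb = find(i), find(k)
                if ra != rb:
                    parent[rb] = ra
    ref = np.array([find(i) for i in range(n)])

    from sklearn.metrics import rand_score

    best_idx, best_val = 0, -1.0
    for idx, z in enumerate(draws.z):
        val = rand_score(ref, z)
        if val > best_val:
            best_idx, best_val = idx, val
    return sim, draws.z[best_idx].copy()
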