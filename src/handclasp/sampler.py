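"""Adaptive Metropolis-within-Gibbs sampler for the handclasp model.

The sampler mirrors the Gibbs-style samplers classically used for this model
family: preference vectors, influence random effects, and influence
coefficients are updated by random-walk Metropolis steps whose scales adapt
during burn-in (Robbins-Monro, frozen afterwards), while the group mean
preferences mu_jk are conjugate-normal Gibbs draws.  The latent chooser
indicators are marginalized analytically in the event likelihood, so no
discrete imputation step is needed; per-event situation probabilities can be
recovered afterwards from the posterior draws (see
:func:`handclasp.inference.impute_choosers`).

All chains advance in lockstep: state arrays carry a leading chain axis and
every proposal/accept step is vectorized across chains, drawing from a single
master-seeded generator.  Because the likelihood factorizes over events, per
block updates only touch the events adjacent to the block, with per-event
log-probability caches kept incrementally (and verifiable against a full
recomputation, see :meth:`GibbsSampler.refresh_caches`).

A non-obvious but important extra move: the chooser probabilities are
invariant under adding a constant to beta_a and to every influence random
effect simultaneously (only exp-scale ratios matter).  A dedicated
translation move proposes exactly that shift, which decorrelates beta_a from
the random-effect mean and removes the main slow direction of the posterior.
"""

from __future__ import annotations

import numpy as np

from .model import ModelArrays, ModelSpec, YOUNG, OLD



def _trunc_sd_gibbs(n: int, SS: np.ndarray, upper: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw sd from p(sd) ∝ sd^-n exp(-SS / (2 sd^2)) on (0, upper).

    Equivalent to sd^2 ~ InvGamma((n-1)/2, SS/2) truncated above at upper^2.
    """
    shape = (n - 1) / 2.0
    sd = np.sqrt(0.5 * SS / rng.gamma(shape, 1.0, size=SS.shape))
    bad = sd >= upper
    for _ in range(200):
        if not bad.any():
            break
        sd[bad] = np.sqrt(0.5 * SS[bad] / rng.gamma(shape, 1.0, size=int(bad.sum())))
        bad = sd >= upper
    return np.minimum(sd, upper * (1.0 - 1e-12))


def _ell_terms(lp1, lp2, la, lb, lc, conc):
    """Per-event log likelihood with the chooser marginalized (vectorized)."""
    both = la + lp1 + lp2
    out = both.copy()
    if conc.any():
        t1 = both[..., conc]
        t2 = lb[..., conc] + lp1[..., conc]
        t3 = lc[..., conc] + lp2[..., conc]
        mx = np.maximum(np.maximum(t1, t2), t3)
        out[..., conc] = mx + np.log(
            np.exp(t1 - mx) + np.exp(t2 - mx) + np.exp(t3 - mx))
    return out


class GibbsSampler:
    """One lockstep batch of MCMC chains for a compiled model."""

    def __init__(self, arrays: ModelArrays, n_chains: int, rng: np.random.Generator):
        self.a = arrays
        self.spec: ModelSpec = arrays.spec
        self.C = n_chains
        self.rng = rng
        C, S, N, J = n_chains, arrays.n_slots, arrays.n_individuals, arrays.n_groups
        A = arrays.n_sigma

        # --- state (modest overdispersion across chains) -------------------
        self.mu = np.zeros((C, J, 5))
        self.mu[:, :, 1:] = rng.normal(0.0, 1.5, size=(C, J, 4))
        self.beta = rng.normal(0.0, 0.5, size=(C, 4))
        self.sigw = rng.uniform(0.5, 2.5, size=(C, A))
        self.sigi = rng.uniform(0.2, 1.0, size=C)
        self.re = rng.normal(0.0, 0.3, size=(C, N))
        self.m = rng.uniform(0.05, 0.95, size=(C, 2))
        self.W = np.zeros((C, S, 5))
        if S:
            base = self.mu[:, arrays.slot_group, 1:]
            sd = self.sigw[:, arrays.slot_sigma_idx][:, :, None]
            self.W[:, :, 1:] = base + sd * rng.normal(size=(C, S, 4))

        # --- adaptive step sizes -------------------------------------------
        self.step_W = np.full((C, S), 0.5)
        self.step_re = np.full((C, N), 0.5)
        self.step_beta = np.full((C, 4), 0.3)
        self.step_shift = np.full(C, 0.3)
        self.step_rc = np.full((C, J), 0.2)
        self.step_m = np.full((C, 2), 0.2)
        # running per-component posterior scale for shaped W proposals
        self._W_count = 0
        self._W_mean = np.zeros((C, S, 4))
        self._W_m2 = np.zeros((C, S, 4))
        self.W_scale = np.ones((C, S, 4))
        self._sweep_count = 0
        self.adapting = True

        # per-block event indices split by concordance: for a discordant
        # event only the independent-choice term survives, so likelihood
        # deltas reduce to simple differences without any logsumexp
        a = arrays
        self._slot_idx = []
        for s in range(S):
            e0, e1 = a.slot_events[s]
            self._slot_idx.append((
                e0[~a.concordant[e0]], a.y1[e0[~a.concordant[e0]]],
                e0[a.concordant[e0]], a.y1[e0[a.concordant[e0]]],
                e1[~a.concordant[e1]], a.y2[e1[~a.concordant[e1]]],
                e1[a.concordant[e1]], a.y2[e1[a.concordant[e1]]],
            ))
        self._indiv_idx = []
        for i in range(N):
            e0, e1 = a.indiv_events[i]
            ev = np.concatenate([e0, e1])
            own1 = np.zeros(len(ev), dtype=bool)
            own1[: len(e0)] = True
            cmask = a.concordant[ev]
            self._indiv_idx.append((ev, own1, cmask))
        # per-group event/slot indices for the recentering move
        self._group_idx = []
        for j in range(J):
            slots_j = np.flatnonzero(a.slot_group == j)
            local = -np.ones(S, dtype=np.int64)
            local[slots_j] = np.arange(len(slots_j))
            if a.n_events:
                evj = np.flatnonzero(a.slot_group[a.s1] == j)
            else:
                evj = np.zeros(0, dtype=np.int64)
            evd = evj[~a.concordant[evj]]
            evc = evj[a.concordant[evj]]
            self._group_idx.append((
                slots_j,
                evd, local[a.s1[evd]], a.y1[evd], local[a.s2[evd]], a.y2[evd],
                evc, local[a.s1[evc]], a.y1[evc], local[a.s2[evc]], a.y2[evc]))

        self.refresh_caches()

    # ------------------------------------------------------------------
    # caches
    # ------------------------------------------------------------------
    def refresh_caches(self) -> None:
        """Recompute every per-event cache from the current state."""
        a = self.a
        z = self.W - self.W.max(axis=2, keepdims=True)
        self.logP = z - np.log(np.exp(z).sum(axis=2, keepdims=True))  # (C,S,5)
        if a.n_events == 0:
            E = 0
            self.lp1 = self.lp2 = np.zeros((self.C, E))
            self.li1 = self.li2 = np.zeros((self.C, E))
            self.la = self.lb = self.lc = np.zeros((self.C, E))
            self.ell = np.zeros((self.C, E))
            return
        self.lp1 = self.logP[:, a.s1, a.y1]
        self.lp2 = self.logP[:, a.s2, a.y2]
        bcov = self.beta[:, 1:]                          # (C,3)
        self.li1 = self.re[:, a.i1] + bcov @ a.X1.T
        self.li2 = self.re[:, a.i2] + bcov @ a.X2.T
        self._recompute_pi()
        self.ell = _ell_terms(self.lp1, self.lp2, self.la, self.lb, self.lc,
                              a.concordant)

    def _recompute_pi(self) -> None:
        ba = self.beta[:, :1]
        lD = np.logaddexp(ba, np.logaddexp(self.li1, self.li2))
        self.la = ba - lD
        self.lb = self.li1 - lD
        self.lc = self.li2 - lD

    def total_loglik(self) -> np.ndarray:
        """Sum of the per-event marginal log likelihood, per chain."""
        return self.ell.sum(axis=1)

    # ------------------------------------------------------------------
    # helpers
    # ------------------------------------------------------------------
    def _slot_prior_mean(self, s: int) -> np.ndarray:
        """Prior mean of slot s's free entries, shape (C, 4)."""
        a = self.a
        base = self.mu[:, a.slot_group[s], 1:]
        mo = a.slot_mother[s]
        if mo >= 0:
            mm = self.m[:, a.slot_mcat[s]][:, None]
            return (1 - mm) * base + mm * self.W[:, mo, 1:]
        return base

    def _prior_means(self) -> np.ndarray:
        """Prior means for all slots, shape (C, S, 4)."""
        a = self.a
        mean = self.mu[:, a.slot_group, 1:].copy()
        has = np.flatnonzero(a.slot_mother >= 0)
        if len(has):
            mm = self.m[:, a.slot_mcat[has]][:, :, None]
            mean[:, has] = (1 - mm) * mean[:, has] + mm * self.W[:, a.slot_mother[has], 1:]
        return mean

    def _adapt(self, step: np.ndarray, accepted: np.ndarray, target: float) -> None:
        if not self.adapting:
            return
        gamma = 1.0 / np.sqrt(10.0 + self._sweep_count)
        np.multiply(step, np.exp(gamma * (accepted - target)), out=step)
        np.clip(step, 1e-3, 1e3, out=step)

    # ------------------------------------------------------------------
    # block updates
    # ------------------------------------------------------------------
    def update_W(self) -> None:
        a, C = self.a, self.C
        S = a.n_slots
        if S == 0:
            return
        Z = self.rng.standard_normal((S, C, 4))
        logU = np.log(self.rng.random((S, C)))
        for s in range(S):
            prop = self.W[:, s, :].copy()
            prop[:, 1:] += self.step_W[:, s, None] * self.W_scale[:, s] * Z[s]
            z = prop - prop.max(axis=1, keepdims=True)
            logPs = z - np.log(np.exp(z).sum(axis=1, keepdims=True))   # (C,5)

            e0d, y0d, e0c, y0c, e1d, y1d, e1c, y1c = self._slot_idx[s]
            dlik = 0.0
            updates = []
            if len(e0d):   # discordant, performer 1: delta is just the lp shift
                lpn = logPs[:, y0d]
                dlik = dlik + (lpn - self.lp1[:, e0d]).sum(axis=1)
                updates.append((self.lp1, e0d, lpn, None))
            if len(e0c):
                lpn = logPs[:, y0c]
                t1 = self.la[:, e0c] + lpn + self.lp2[:, e0c]
                t2 = self.lb[:, e0c] + lpn
                t3 = self.lc[:, e0c] + self.lp2[:, e0c]
                mx = np.maximum(np.maximum(t1, t2), t3)
                elln = mx + np.log(np.exp(t1 - mx) + np.exp(t2 - mx) + np.exp(t3 - mx))
                dlik = dlik + (elln - self.ell[:, e0c]).sum(axis=1)
                updates.append((self.lp1, e0c, lpn, elln))
            if len(e1d):
                lpn = logPs[:, y1d]
                dlik = dlik + (lpn - self.lp2[:, e1d]).sum(axis=1)
                updates.append((self.lp2, e1d, lpn, None))
            if len(e1c):
                lpn = logPs[:, y1c]
                t1 = self.la[:, e1c] + self.lp1[:, e1c] + lpn
                t2 = self.lb[:, e1c] + self.lp1[:, e1c]
                t3 = self.lc[:, e1c] + lpn
                mx = np.maximum(np.maximum(t1, t2), t3)
                elln = mx + np.log(np.exp(t1 - mx) + np.exp(t2 - mx) + np.exp(t3 - mx))
                dlik = dlik + (elln - self.ell[:, e1c]).sum(axis=1)
                updates.append((self.lp2, e1c, lpn, elln))

            pm = self._slot_prior_mean(s)
            sd2 = self.sigw[:, a.slot_sigma_idx[s]] ** 2
            dpr = -0.5 * (((prop[:, 1:] - pm) ** 2
                           - (self.W[:, s, 1:] - pm) ** 2).sum(axis=1)) / sd2
            for ch in a.children[s]:
                mm = self.m[:, a.slot_mcat[ch]][:, None]
                basec = self.mu[:, a.slot_group[ch], 1:]
                sdc2 = self.sigw[:, a.slot_sigma_idx[ch]] ** 2
                Wc = self.W[:, ch, 1:]
                mn = (1 - mm) * basec + mm * prop[:, 1:]
                mo_ = (1 - mm) * basec + mm * self.W[:, s, 1:]
                dpr += -0.5 * (((Wc - mn) ** 2 - (Wc - mo_) ** 2).sum(axis=1)) / sdc2

            acc = logU[s] < dlik + dpr
            if acc.any():
                r = np.flatnonzero(acc)
                rc = r[:, None]
                self.W[r, s] = prop[r]
                self.logP[r, s] = logPs[r]
                for cache, ev, lpn, elln in updates:
                    if elln is None:
                        self.ell[rc, ev] += lpn[r] - cache[rc, ev]
                    else:
                        self.ell[rc, ev] = elln[r]
                    cache[rc, ev] = lpn[r]
            self._adapt(self.step_W[:, s], acc.astype(float), 0.28)

    def update_re(self) -> None:
        a, C = self.a, self.C
        N = a.n_individuals
        if N == 0:
            return
        Z = self.rng.standard_normal((N, C))
        logU = np.log(self.rng.random((N, C)))
        ba = self.beta[:, :1]
        for i in range(N):
            ev, own1, cmask = self._indiv_idx[i]
            dz = self.step_re[:, i] * Z[i]
            prop = self.re[:, i] + dz
            dpr = -0.5 * (prop ** 2 - self.re[:, i] ** 2) / self.sigi ** 2
            if len(ev):
                li1n = self.li1[:, ev].copy()
                li2n = self.li2[:, ev].copy()
                li1n[:, own1] += dz[:, None]
                li2n[:, ~own1] += dz[:, None]
                lD = np.logaddexp(ba, np.logaddexp(li1n, li2n))
                lan = ba - lD
                lbn = li1n - lD
                lcn = li2n - lD
                # discordant events: ell = la + lp1 + lp2, so only la shifts
                elln = lan + self.lp1[:, ev] + self.lp2[:, ev]
                if cmask.any():
                    t1 = elln[:, cmask]
                    t2 = lbn[:, cmask] + self.lp1[:, ev[cmask]]
                    t3 = lcn[:, cmask] + self.lp2[:, ev[cmask]]
                    mx = np.maximum(np.maximum(t1, t2), t3)
                    elln[:, cmask] = mx + np.log(
                        np.exp(t1 - mx) + np.exp(t2 - mx) + np.exp(t3 - mx))
                dlik = (elln - self.ell[:, ev]).sum(axis=1)
            else:
                dlik = 0.0
            acc = logU[i] < dlik + dpr
            if acc.any():
                r = np.flatnonzero(acc)
                self.re[r, i] = prop[r]
                if len(ev):
                    rc = r[:, None]
                    self.li1[rc, ev] = li1n[r]
                    self.li2[rc, ev] = li2n[r]
                    self.la[rc, ev] = lan[r]
                    self.lb[rc, ev] = lbn[r]
                    self.lc[rc, ev] = lcn[r]
                    self.ell[rc, ev] = elln[r]
            self._adapt(self.step_re[:, i], acc.astype(float), 0.44)

    def update_beta(self) -> None:
        a, C, rng = self.a, self.C, self.rng
        conc = a.concordant
        sd0 = self.spec.mu_prior_sd
        for b in range(4):
            db = self.step_beta[:, b] * rng.standard_normal(C)
            prop = self.beta[:, b] + db
            dpr = -0.5 * (prop ** 2 - self.beta[:, b] ** 2) / sd0 ** 2
            if a.n_events:
                if b == 0:
                    li1n, li2n = self.li1, self.li2
                    ban = prop[:, None]
                else:
                    li1n = self.li1 + db[:, None] * a.X1[:, b - 1][None, :]
                    li2n = self.li2 + db[:, None] * a.X2[:, b - 1][None, :]
                    ban = self.beta[:, :1]
                lD = np.logaddexp(ban, np.logaddexp(li1n, li2n))
                lan, lbn, lcn = ban - lD, li1n - lD, li2n - lD
                elln = _ell_terms(self.lp1, self.lp2, lan, lbn, lcn, conc)
                dlik = (elln - self.ell).sum(axis=1)
            else:
                dlik = np.zeros(C)
            acc = np.log(rng.random(C)) < dlik + dpr
            if acc.any():
                r = np.flatnonzero(acc)
                self.beta[r, b] = prop[r]
                if a.n_events:
                    if b != 0:
                        self.li1[r] = li1n[r]
                        self.li2[r] = li2n[r]
                    self.la[r] = lan[r]
                    self.lb[r] = lbn[r]
                    self.lc[r] = lcn[r]
                    self.ell[r] = elln[r]
            self._adapt(self.step_beta[:, b], acc.astype(float), 0.44)

        # translation move: beta_a and all REs shift together; the chooser
        # probabilities (hence the likelihood) are exactly invariant.
        if a.n_individuals:
            t = self.step_shift * rng.standard_normal(C)
            ban = self.beta[:, 0] + t
            dpr = -0.5 * (ban ** 2 - self.beta[:, 0] ** 2) / sd0 ** 2
            ren = self.re + t[:, None]
            dpr += -0.5 * ((ren ** 2 - self.re ** 2).sum(axis=1)) / self.sigi ** 2
            acc = np.log(rng.random(C)) < dpr
            if acc.any():
                r = np.flatnonzero(acc)
                self.beta[r, 0] = ban[r]
                self.re[r] = ren[r]
                if a.n_events:
                    self.li1[r] += t[r, None]
                    self.li2[r] += t[r, None]
            self._adapt(self.step_shift, acc.astype(float), 0.44)

    def update_mu(self) -> None:
        """Conjugate Gibbs draw of the group mean preferences."""
        a, C, rng = self.a, self.C, self.rng
        sd0 = self.spec.mu_prior_sd
        if a.n_slots == 0:
            if a.n_groups:
                self.mu[:, :, 1:] = rng.normal(0.0, sd0, size=(C, a.n_groups, 4))
            return
        coef = np.ones((C, a.n_slots))
        offset = np.zeros((C, a.n_slots, 4))
        has = np.flatnonzero(a.slot_mother >= 0)
        if len(has):
            mm = self.m[:, a.slot_mcat[has]]
            coef[:, has] = 1 - mm
            offset[:, has] = mm[:, :, None] * self.W[:, a.slot_mother[has], 1:]
        sig2 = self.sigw[:, a.slot_sigma_idx] ** 2                    # (C,S)
        wgt = coef ** 2 / sig2
        resid = coef[:, :, None] * (self.W[:, :, 1:] - offset) / sig2[:, :, None]
        for j in range(a.n_groups):
            mask = a.slot_group == j
            prec = 1.0 / sd0 ** 2 + wgt[:, mask].sum(axis=1)           # (C,)
            mean = resid[:, mask].sum(axis=1) / prec[:, None]          # (C,4)
            self.mu[:, j, 1:] = mean + rng.standard_normal((C, 4)) / np.sqrt(prec)[:, None]

    def update_recenter(self) -> None:
        """Shift a group's mean preferences and all its preference vectors
        jointly.

        The preference prior residuals W - mean are invariant under the shift
        (maternal means shift identically because mothers live in the same
        group), so the acceptance ratio is the likelihood change plus the mu
        hyperprior change.  This move samples the group-location direction of
        the posterior, which componentwise random walks traverse slowly for
        rarely performed variants.
        """
        a, C = self.a, self.C
        if a.n_slots == 0:
            return
        sd0 = self.spec.mu_prior_sd
        for j in range(a.n_groups):
            (slots_j, evd, s1d, y1d, s2d, y2d,
             evc, s1c, y1c, s2c, y2c) = self._group_idx[j]
            if len(slots_j) == 0:
                continue
            d = self.step_rc[:, j, None] * self.rng.standard_normal((C, 4))
            Wn = self.W[:, slots_j, :].copy()
            Wn[:, :, 1:] += d[:, None, :]
            z = Wn - Wn.max(axis=2, keepdims=True)
            logPn = z - np.log(np.exp(z).sum(axis=2, keepdims=True))
            dlik = 0.0
            if len(evd):
                lp1n = logPn[:, s1d, y1d]
                lp2n = logPn[:, s2d, y2d]
                delld = (lp1n - self.lp1[:, evd]) + (lp2n - self.lp2[:, evd])
                dlik = dlik + delld.sum(axis=1)
            if len(evc):
                lp1c = logPn[:, s1c, y1c]
                lp2c = logPn[:, s2c, y2c]
                t1 = self.la[:, evc] + lp1c + lp2c
                t2 = self.lb[:, evc] + lp1c
                t3 = self.lc[:, evc] + lp2c
                mx = np.maximum(np.maximum(t1, t2), t3)
                ellc = mx + np.log(np.exp(t1 - mx) + np.exp(t2 - mx) + np.exp(t3 - mx))
                dlik = dlik + (ellc - self.ell[:, evc]).sum(axis=1)
            mun = self.mu[:, j, 1:] + d
            dpr = -0.5 * ((mun ** 2 - self.mu[:, j, 1:] ** 2).sum(axis=1)) / sd0 ** 2
            acc = np.log(self.rng.random(C)) < dlik + dpr
            if acc.any():
                r = np.flatnonzero(acc)
                rc = r[:, None]
                self.W[np.ix_(r, slots_j)] = Wn[r]
                self.logP[np.ix_(r, slots_j)] = logPn[r]
                self.mu[r, j, 1:] = mun[r]
                if len(evd):
                    self.ell[rc, evd] += delld[r]
                    self.lp1[rc, evd] = lp1n[r]
                    self.lp2[rc, evd] = lp2n[r]
                if len(evc):
                    self.ell[rc, evc] = ellc[r]
                    self.lp1[rc, evc] = lp1c[r]
                    self.lp2[rc, evc] = lp2c[r]
            self._adapt(self.step_rc[:, j], acc.astype(float), 0.28)

    def update_sigmas(self) -> None:
        """Gibbs draws of the sigma parameters.

        Under the flat Uniform(0, upper) prior the conditional of sigma^2 is
        a truncated inverse-gamma; drawing it directly (rejection for the
        truncation, which essentially never triggers away from the bound)
        mixes far better than a random walk on sigma.
        """
        a, C, rng = self.a, self.C, self.rng
        upper = self.spec.sigma_upper
        if a.n_slots:
            pm = self._prior_means()
            resid2 = (self.W[:, :, 1:] - pm) ** 2
        for cat in range(a.n_sigma):
            n = int((a.slot_sigma_idx == cat).sum()) * 4 if a.n_slots else 0
            if n == 0:
                self.sigw[:, cat] = rng.uniform(0.0, upper, C)
                continue
            SS = resid2[:, a.slot_sigma_idx == cat].sum(axis=(1, 2))
            self.sigw[:, cat] = _trunc_sd_gibbs(n, SS, upper, rng)
        if a.n_individuals >= 2:
            self.sigi = _trunc_sd_gibbs(a.n_individuals,
                                        (self.re ** 2).sum(axis=1), upper, rng)
        elif a.n_individuals == 1:
            # degenerate single-individual case: one slice-like Metropolis step
            prop = self.sigi + 0.5 * rng.standard_normal(C)
            ok = (prop > 0) & (prop < upper)
            r2 = (self.re ** 2).sum(axis=1)
            with np.errstate(all="ignore"):
                delta = -(np.log(np.abs(prop)) - np.log(self.sigi)) \
                    - 0.5 * r2 * (1.0 / prop ** 2 - 1.0 / self.sigi ** 2)
            acc = ok & (np.log(rng.random(C)) < delta)
            self.sigi[acc] = prop[acc]
        else:
            self.sigi = rng.uniform(0.0, upper, C)

    def update_m(self) -> None:
        if not self.spec.maternal:
            return
        a, C, rng = self.a, self.C, self.rng
        for cat in (YOUNG, OLD):
            cur = self.m[:, cat]
            prop = cur + self.step_m[:, cat] * rng.standard_normal(C)
            ok = (prop >= 0) & (prop <= 1)
            delta = np.where(ok, 0.0, -np.inf)
            sl = np.flatnonzero((a.slot_mcat == cat) & (a.slot_mother >= 0))
            if len(sl):
                base = self.mu[:, a.slot_group[sl], 1:]
                Wm = self.W[:, a.slot_mother[sl], 1:]
                Ws = self.W[:, sl, 1:]
                sd2 = self.sigw[:, a.slot_sigma_idx[sl]] ** 2
                mn_new = (1 - prop[:, None, None]) * base + prop[:, None, None] * Wm
                mn_old = (1 - cur[:, None, None]) * base + cur[:, None, None] * Wm
                d = -0.5 * (((Ws - mn_new) ** 2 - (Ws - mn_old) ** 2).sum(axis=2)
                            / sd2).sum(axis=1)
                delta = delta + np.where(ok, d, 0.0)
            acc = ok & (np.log(rng.random(C)) < delta)
            self.m[acc, cat] = prop[acc]
            self._adapt(self.step_m[:, cat], acc.astype(float), 0.44)

    # ------------------------------------------------------------------
    def sweep(self) -> None:
        self.update_W()
        self.update_re()
        self.update_beta()
        self.update_mu()
        self.update_recenter()
        self.update_sigmas()
        self.update_m()
        if self.adapting and self.a.n_slots:
            # running posterior spread per W component shapes the proposals
            self._W_count += 1
            x = self.W[:, :, 1:]
            delta = x - self._W_mean
            self._W_mean += delta / self._W_count
            self._W_m2 += delta * (x - self._W_mean)
            if self._W_count >= 50 and self._W_count % 25 == 0:
                sd = np.sqrt(self._W_m2 / self._W_count)
                self.W_scale = np.clip(sd, 0.1, 10.0)
        self._sweep_count += 1
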