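"""Compiled (numba) inner loops of the block Metropolis-Hastings sweep.

Each kernel mirrors one reference update in :mod:`cocoondyn.mcmc` exactly:
same proposal transforms, same acceptance rule, and it consumes externally
drawn noise/uniform arrays in the same element order, so the two paths can
be compared draw for draw in tests.  Kernels mutate the state arrays (and
the log-space caches of the latent variables) in place and return
``(n_accepted, n_proposed)``.

Index conventions: state arrays are ``(C, S, J, T)`` with a leading chain
axis; ``first[i, t]`` marks site i's first observed year, where the
carryover uses the dummy rate ``kappa0`` and, under ``zero_history``, the
pools are fixed at zero.
"""

import math

import numpy as np
from numba import njit


@njit(cache=False)
def cells_update(parity, N, TH, KA, K0, PI, PM, PH,
                 LN, LTH, L1TH, LKA, L1KA,
                 PHI, S_, NM, KT, KK, PT, PK,
                 yI, yM, yH, mask, first,
                 lstep, step, noise, unif, gain, target,
                 phi_on_fresh, zero_history, floor):
    C, S, J, T = N.shape
    n_acc = 0
    n_tot = 0
    for c in range(C):
        phi = PHI[c]
        s = S_[c]
        kt = KT[c]
        kk = KK[c]
        for i in range(S):
            for j in range(J):
                for t in range(parity, T, 2):
                    n_tot += 1
                    st = step[c, i, j, t]
                    n = N[c, i, j, t]
                    th = TH[c, i, j, t]
                    ka = KA[c, i, j, t]
                    zn = LN[c, i, j, t]
                    lth = LTH[c, i, j, t]
                    l1th = L1TH[c, i, j, t]
                    lka = LKA[c, i, j, t]
                    l1ka = L1KA[c, i, j, t]
                    zn2 = zn + st * noise[0, c, i, j, t]
                    zt2 = (lth - l1th) + st * noise[1, c, i, j, t]
                    zk2 = (lka - l1ka) + st * noise[2, c, i, j, t]
                    n2 = math.exp(zn2)
                    th2 = 1.0 / (1.0 + math.exp(-zt2))
                    ka2 = 1.0 / (1.0 + math.exp(-zk2))
                    accept = False
                    if (n2 > 0.0 and math.isfinite(n2)
                            and 0.0 < th2 < 1.0 and 0.0 < ka2 < 1.0):
                        lth2 = math.log(th2)
                        l1th2 = math.log1p(-th2)
                        lka2 = math.log(ka2)
                        l1ka2 = math.log1p(-ka2)
                        delta = 0.0
                        m = mask[c, i, j, t]
                        if m > 0.0:
                            if first[i, t]:
                                kprev = K0[c, i, j]
                            else:
                                kprev = KA[c, i, j, t - 1]
                            if zero_history and first[i, t]:
                                pI = 0.0
                                pM = 0.0
                            else:
                                pI = PI[c, i, j, t]
                                pM = PM[c, i, j, t]
                            if phi_on_fresh:
                                carry = phi * (kprev * pI + pM)
                            else:
                                carry = kprev * pI + phi * pM
                            lamI = n * (1.0 - th)
                            lamI2 = n2 * (1.0 - th2)
                            lamM = n * th + carry
                            lamM2 = n2 * th2 + carry
                            if zero_history:
                                if lamM < floor:
                                    lamM = floor
                                if lamM2 < floor:
                                    lamM2 = floor
                            d = -(lamI2 - lamI) - (lamM2 - lamM)
                            y = yI[c, i, j, t]
                            if y > 0.0:
                                d += y * (math.log(lamI2) - math.log(lamI))
                            y = yM[c, i, j, t]
                            if y > 0.0:
                                d += y * (math.log(lamM2) - math.log(lamM))
                            delta += m * d
                        tn = t + 1
                        if tn < T and mask[c, i, j, tn] > 0.0 and not first[i, tn]:
                            pIn = PI[c, i, j, tn]
                            pMn = PM[c, i, j, tn]
                            pHn = PH[c, i, j, tn]
                            A = N[c, i, j, tn] * TH[c, i, j, tn]
                            if phi_on_fresh:
                                lamMn = A + phi * (ka * pIn + pMn)
                                lamMn2 = A + phi * (ka2 * pIn + pMn)
                                lamHn = phi * ((1.0 - ka) * pIn + pHn)
                                lamHn2 = phi * ((1.0 - ka2) * pIn + pHn)
                            else:
                                lamMn = A + ka * pIn + phi * pMn
                                lamMn2 = A + ka2 * pIn + phi * pMn
                                lamHn = (1.0 - ka) * pIn + phi * pHn
                                lamHn2 = (1.0 - ka2) * pIn + phi * pHn
                            if zero_history:
                                if lamMn < floor:
                                    lamMn = floor
                                if lamMn2 < floor:
                                    lamMn2 = floor
                                if lamHn < floor:
                                    lamHn = floor
                                if lamHn2 < floor:
                                    lamHn2 = floor
                            d = -(lamMn2 - lamMn) - (lamHn2 - lamHn)
                            y = yM[c, i, j, tn]
                            if y > 0.0:
                                d += y * (math.log(lamMn2) - math.log(lamMn))
                            y = yH[c, i, j, tn]
                            if y > 0.0:
                                d += y * (math.log(lamHn2) - math.log(lamHn))
                            delta += mask[c, i, j, tn] * d
                        # priors (normalizing constants cancel within blocks)
                        a = NM[c, i, t] / s
                        delta += (a - 1.0) * (zn2 - zn) - (n2 - n) / s
                        pth = PT[c, i, t]
                        delta += ((kt * pth - 1.0) * (lth2 - lth)
                                  + (kt * (1.0 - pth) - 1.0) * (l1th2 - l1th))
                        pka = PK[c, i, t]
                        delta += ((kk * pka - 1.0) * (lka2 - lka)
                                  + (kk * (1.0 - pka) - 1.0) * (l1ka2 - l1ka))
                        # jacobians of the log / logit transforms
                        delta += (zn2 - zn)
                        delta += (lth2 + l1th2) - (lth + l1th)
                        delta += (lka2 + l1ka2) - (lka + l1ka)
                        accept = math.log(unif[c, i, j, t]) < delta
                    if accept:
                        n_acc += 1
                        N[c, i, j, t] = n2
                        TH[c, i, j, t] = th2
                        KA[c, i, j, t] = ka2
                        LN[c, i, j, t] = zn2
                        LTH[c, i, j, t] = lth2
                        L1TH[c, i, j, t] = l1th2
                        LKA[c, i, j, t] = lka2
                        L1KA[c, i, j, t] = l1ka2
                    if gain > 0.0:
                        ls = lstep[c, i, j, t] + gain * ((1.0 if accept else 0.0) - target)
                        lstep[c, i, j, t] = ls
                        step[c, i, j, t] = math.exp(ls)
    return n_acc, n_tot


@njit(cache=False)
def pools_update(PI, PM, PH, K0, N, TH, KA, PHI,
                 LPI, LPM, LPH, LK0, L1K0,
                 pool_a, pool_b, yM, yH, mask, first,
                 lstep, step, lstep0, step0,
                 noise, noise0, unif, gain, target,
                 phi_on_fresh, zero_history, floor):
    C, S, J, T = N.shape
    n_acc = 0
    n_tot = 0
    for c in range(C):
        phi = PHI[c]
        for i in range(S):
            for j in range(J):
                for t in range(T):
                    isf = first[i, t]
                    if zero_history and isf:
                        continue                   # fixed at zero
                    n_tot += 1
                    st = step[c, i, j, t]
                    pI = PI[c, i, j, t]
                    pM = PM[c, i, j, t]
                    pH = PH[c, i, j, t]
                    zI = LPI[c, i, j, t]
                    zM = LPM[c, i, j, t]
                    zH = LPH[c, i, j, t]
                    zI2 = zI + st * noise[0, c, i, j, t]
                    zM2 = zM + st * noise[1, c, i, j, t]
                    zH2 = zH + st * noise[2, c, i, j, t]
                    pI2 = math.exp(zI2)
                    pM2 = math.exp(zM2)
                    pH2 = math.exp(zH2)
                    k0 = K0[c, i, j]
                    k02 = k0
                    lk02 = 0.0
                    l1k02 = 0.0
                    ok = (pI2 > 0.0 and math.isfinite(pI2)
                          and pM2 > 0.0 and math.isfinite(pM2)
                          and pH2 > 0.0 and math.isfinite(pH2))
                    if ok and isf:
                        z0 = LK0[c, i, j] - L1K0[c, i, j]
                        z02 = z0 + step0[c, i, j] * noise0[c, i, j]
                        k02 = 1.0 / (1.0 + math.exp(-z02))
                        if not (0.0 < k02 < 1.0):
                            ok = False
                        else:
                            lk02 = math.log(k02)
                            l1k02 = math.log1p(-k02)
                    accept = False
                    if ok:
                        if isf:
                            kprev = k0
                            kprev2 = k02
                        else:
                            kprev = KA[c, i, j, t - 1]
                            kprev2 = kprev
                        nn = N[c, i, j, t]
                        th = TH[c, i, j, t]
                        A = nn * th
                        if phi_on_fresh:
                            lamM = A + phi * (kprev * pI + pM)
                            lamM2 = A + phi * (kprev2 * pI2 + pM2)
                            lamH = phi * ((1.0 - kprev) * pI + pH)
                            lamH2 = phi * ((1.0 - kprev2) * pI2 + pH2)
                        else:
                            lamM = A + kprev * pI + phi * pM
                            lamM2 = A + kprev2 * pI2 + phi * pM2
                            lamH = (1.0 - kprev) * pI + phi * pH
                            lamH2 = (1.0 - kprev2) * pI2 + phi * pH2
                        if zero_history:
                            if lamM < floor:
                                lamM = floor
                            if lamM2 < floor:
                                lamM2 = floor
                            if lamH < floor:
                                lamH = floor
                            if lamH2 < floor:
                                lamH2 = floor
                        m = mask[c, i, j, t]
                        d = -(lamM2 - lamM) - (lamH2 - lamH)
                        y = yM[c, i, j, t]
                        if y > 0.0:
                            d += y * (math.log(lamM2) - math.log(lamM))
                        y = yH[c, i, j, t]
                        if y > 0.0:
                            d += y * (math.log(lamH2) - math.log(lamH))
                        delta = m * d
                        # moment-matched gamma priors + log jacobians
                        delta += ((pool_a[0, c, i, t] - 1.0) * (zI2 - zI)
                                  - pool_b[0, c, i, t] * (pI2 - pI) + (zI2 - zI))
                        delta += ((pool_a[1, c, i, t] - 1.0) * (zM2 - zM)
                                  - pool_b[1, c, i, t] * (pM2 - pM) + (zM2 - zM))
                        delta += ((pool_a[2, c, i, t] - 1.0) * (zH2 - zH)
                                  - pool_b[2, c, i, t] * (pH2 - pH) + (zH2 - zH))
                        if isf:
                            delta += (lk02 + l1k02) - (LK0[c, i, j] + L1K0[c, i, j])
                        accept = math.log(unif[c, i, j, t]) < delta
                    if accept:
                        n_acc += 1
                        PI[c, i, j, t] = pI2
                        PM[c, i, j, t] = pM2
                        PH[c, i, j, t] = pH2
                        LPI[c, i, j, t] = zI2
                        LPM[c, i, j, t] = zM2
                        LPH[c, i, j, t] = zH2
                        if isf:
                            K0[c, i, j] = k02
                            LK0[c, i, j] = lk02
                            L1K0[c, i, j] = l1k02
                    if gain > 0.0:
                        ls = lstep[c, i, j, t] + gain * ((1.0 if accept else 0.0) - target)
                        lstep[c, i, j, t] = ls
                        step[c, i, j, t] = math.exp(ls)
                        if isf:
                            l0 = lstep0[c, i, j] + gain * ((1.0 if accept else 0.0) - target)
                            lstep0[c, i, j] = l0
                            step0[c, i, j] = math.exp(l0)
    return n_acc, n_tot


@njit(cache=False)
def site_rate_update(P, K, LAT_L, LAT_L1, lstep, step, noise, unif,
                     gain, target):
    C, S, T = P.shape
    J = LAT_L.shape[2]
    n_acc = 0
    n_tot = 0
    for c in range(C):
        k = K[c]
        for i in range(S):
            for t in range(T):
                n_tot += 1
                p = P[c, i, t]
                z = math.log(p) - math.log1p(-p)
                z2 = z + step[c, i, t] * noise[c, i, t]
                p2 = 1.0 / (1.0 + math.exp(-z2))
                accept = False
                if 0.0 < p2 < 1.0:
                    sl = 0.0
                    sl1 = 0.0
                    for j in range(J):
                        sl += LAT_L[c, i, j, t]
                        sl1 += LAT_L1[c, i, j, t]
                    a = k * p
                    b = k * (1.0 - p)
                    a2 = k * p2
                    b2 = k * (1.0 - p2)
                    delta = (J * (math.lgamma(a) + math.lgamma(b)
                                  - math.lgamma(a2) - math.lgamma(b2))
                             + (a2 - a) * sl + (b2 - b) * sl1
                             + math.log(p2) + math.log1p(-p2)
                             - math.log(p) - math.log1p(-p))
                    accept = math.log(unif[c, i, t]) < delta
                if accept:
                    n_acc += 1
                    P[c, i, t] = p2
                if gain > 0.0:
                    ls = lstep[c, i, t] + gain * ((1.0 if accept else 0.0) - target)
                    lstep[c, i, t] = ls
                    step[c, i, t] = math.exp(ls)
    return n_acc, n_tot


@njit(cache=False)
def _pos_lp(x, fam, a, b):
    """('gamma', shape, rate) or ('invgamma', shape, scale) log-density."""
    if fam == 0:
        return a * math.log(b) - math.lgamma(a) + (a - 1.0) * math.log(x) - b * x
    return a * math.log(b) - math.lgamma(a) - (a + 1.0) * math.log(x) - b / x


@njit(cache=False)
def n_mean_update(NM, S_, LN, lstep, step, noise, unif, gain, target,
                  fam, pa, pb):
    C, S, T = NM.shape
    J = LN.shape[2]
    n_acc = 0
    n_tot = 0
    for c in range(C):
        s = S_[c]
        lb = math.log(1.0 / s)
        for i in range(S):
            for t in range(T):
                n_tot += 1
                nm = NM[c, i, t]
                z = math.log(nm)
                z2 = z + step[c, i, t] * noise[c, i, t]
                nm2 = math.exp(z2)
                accept = False
                if nm2 > 0.0 and math.isfinite(nm2):
                    sln = 0.0
                    for j in range(J):
                        sln += LN[c, i, j, t]
                    a = nm / s
                    a2 = nm2 / s
                    delta = (J * ((a2 - a) * lb
                                  - (math.lgamma(a2) - math.lgamma(a)))
                             + (a2 - a) * sln
                             + _pos_lp(nm2, fam, pa, pb)
                             - _pos_lp(nm, fam, pa, pb)
                             + (z2 - z))
                    accept = math.log(unif[c, i, t]) < delta
                if accept:
                    n_acc += 1
                    NM[c, i, t] = nm2
                if gain > 0.0:
                    ls = lstep[c, i, t] + gain * ((1.0 if accept else 0.0) - target)
                    lstep[c, i, t] = ls
                    step[c, i, t] = math.exp(ls)
    return n_acc, n_tot


@njit(cache=False)
def phi_update(PHI, N, TH, KA, K0, PI, PM, PH, yM, yH, mask, first,
               lstep, step, noise, unif, gain, target,
               phi_on_fresh, zero_history, floor):
    C, S, J, T = N.shape
    n_acc = 0
    for c in range(C):
        phi = PHI[c]
        z = math.log(phi) - math.log1p(-phi)
        z2 = z + step[c] * noise[c]
        phi2 = 1.0 / (1.0 + math.exp(-z2))
        accept = False
        if 0.0 < phi2 < 1.0:
            delta = (math.log(phi2) + math.log1p(-phi2)
                     - math.log(phi) - math.log1p(-phi))
            for i in range(S):
                for j in range(J):
                    for t in range(T):
                        m = mask[c, i, j, t]
                        if m == 0.0:
                            continue
                        if first[i, t]:
                            kprev = K0[c, i, j]
                            if zero_history:
                                pI = 0.0
                                pM = 0.0
                                pH = 0.0
                            else:
                                pI = PI[c, i, j, t]
                                pM = PM[c, i, j, t]
                                pH = PH[c, i, j, t]
                        else:
                            kprev = KA[c, i, j, t - 1]
                            pI = PI[c, i, j, t]
                            pM = PM[c, i, j, t]
                            pH = PH[c, i, j, t]
                        A = N[c, i, j, t] * TH[c, i, j, t]
                        if phi_on_fresh:
                            B = kprev * pI + pM
                            CH = (1.0 - kprev) * pI + pH
                            lamM = A + phi * B
                            lamM2 = A + phi2 * B
                            lamH = phi * CH
                            lamH2 = phi2 * CH
                        else:
                            lamM = A + kprev * pI + phi * pM
                            lamM2 = A + kprev * pI + phi2 * pM
                            lamH = (1.0 - kprev) * pI + phi * pH
                            lamH2 = (1.0 - kprev) * pI + phi2 * pH
                        if zero_history:
                            if lamM < floor:
                                lamM = floor
                            if lamM2 < floor:
                                lamM2 = floor
                            if lamH < floor:
                                lamH = floor
                            if lamH2 < floor:
                                lamH2 = floor
                        d = -(lamM2 - lamM) - (lamH2 - lamH)
                        y = yM[c, i, j, t]
                        if y > 0.0:
                            d += y * (math.log(lamM2) - math.log(lamM))
                        y = yH[c, i, j, t]
                        if y > 0.0:
                            if lamH <= 0.0 or lamH2 <= 0.0:
                                d = -np.inf
                            else:
                                d += y * (math.log(lamH2) - math.log(lamH))
                        delta += m * d
            accept = math.log(unif[c]) < delta
        if accept:
            n_acc += 1
            PHI[c] = phi2
        if gain > 0.0:
            ls = lstep[c] + gain * ((1.0 if accept else 0.0) - target)
            lstep[c] = ls
            step[c] = math.exp(ls)
    return n_acc, C


@njit(cache=False)
def s_update(S_, NM, N, LN, lstep, step, noise, unif, gain, target,
             fam, pa, pb):
    C, S, J, T = N.shape
    n_acc = 0
    for c in range(C):
        s = S_[c]
        z = math.log(s)
        z2 = z + step[c] * noise[c]
        s2 = math.exp(z2)
        accept = False
        if s2 > 0.0 and math.isfinite(s2):
            lb = math.log(1.0 / s)
            lb2 = math.log(1.0 / s2)
            delta = 0.0
            for i in range(S):
                for t in range(T):
                    sln = 0.0
                    sn = 0.0
                    for j in range(J):
                        sln += LN[c, i, j, t]
                        sn += N[c, i, j, t]
                    a = NM[c, i, t] / s
                    a2 = NM[c, i, t] / s2
                    delta += (J * (a2 * lb2 - math.lgamma(a2)
                                   - a * lb + math.lgamma(a))
                              + (a2 - a) * sln - (1.0 / s2 - 1.0 / s) * sn)
            delta += (_pos_lp(s2, fam, pa, pb) - _pos_lp(s, fam, pa, pb)
                      + (z2 - z))
            accept = math.log(unif[c]) < delta
        if accept:
            n_acc += 1
            S_[c] = s2
        if gain > 0.0:
            ls = lstep[c] + gain * ((1.0 if accept else 0.0) - target)
            lstep[c] = ls
            step[c] = math.exp(ls)
    return n_acc, C


@njit(cache=False)
def k_update(K, P, LAT_L, LAT_L1, lstep, step, noise, unif, gain, target,
             fam, pa, pb):
    C, S, T = P.shape
    J = LAT_L.shape[2]
    n_acc = 0
    for c in range(C):
        k = K[c]
        z = math.log(k)
        z2 = z + step[c] * noise[c]
        k2 = math.exp(z2)
        accept = False
        if k2 > 0.0 and math.isfinite(k2):
            delta = 0.0
            lgk = math.lgamma(k)
            lgk2 = math.lgamma(k2)
            for i in range(S):
                for t in range(T):
                    p = P[c, i, t]
                    sl = 0.0
                    sl1 = 0.0
                    for j in range(J):
                        sl += LAT_L[c, i, j, t]
                        sl1 += LAT_L1[c, i, j, t]
                    delta += (J * (lgk2 - math.lgamma(k2 * p)
                                   - math.lgamma(k2 * (1.0 - p))
                                   - lgk + math.lgamma(k * p)
                                   + math.lgamma(k * (1.0 - p)))
                              + (k2 - k) * p * sl
                              + (k2 - k) * (1.0 - p) * sl1)
            delta += (_pos_lp(k2, fam, pa, pb) - _pos_lp(k, fam, pa, pb)
                      + (z2 - z))
            accept = math.log(unif[c]) < delta
        if accept:
            n_acc += 1
            K[c] = k2
        if gain > 0.0:
            ls = lstep[c] + gain * ((1.0 if accept else 0.0) - target)
            lstep[c] = ls
            step[c] = math.exp(ls)
    return n_acc, C
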