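"""Independent scalar reference for the forward model.

A deliberately plain, loop-based transcription of the published PROSPECT-5
plate model and the 4SAIL four-stream canopy solution, written separately
from the package's vectorized kernels and sharing no code with them.  It
serves as the cross-check oracle: both routes are fed the same optical
constants, so agreement checks the model equations rather than the spectra.

Everything here is per-wavelength scalar arithmetic; it is far too slow for
production use and exists only for testing.
"""

import math

from scipy.special import exp1

LITAB = (5.0, 15.0, 25.0, 35.0, 45.0, 55.0, 65.0, 75.0, 81.0, 83.0, 85.0, 87.0, 89.0)
CLASS_EDGES = ((0, 10), (10, 20), (20, 30), (30, 40), (40, 50), (50, 60),
               (60, 70), (70, 80), (80, 82), (82, 84), (84, 86), (86, 88), (88, 90))


def tav_scalar(alpha_deg, n):
    """Stern/Allen average transmissivity of one dielectric interface."""
    rd = math.pi / 180.0
    n2 = n * n
    npp = n2 + 1.0
    nm = n2 - 1.0
    a = (n + 1.0) ** 2 / 2.0
    k = -((n2 - 1.0) ** 2) / 4.0
    sa = math.sin(alpha_deg * rd)
    if alpha_deg != 90.0:
        b1 = math.sqrt((sa * sa - npp / 2.0) ** 2 + k)
    else:
        b1 = 0.0
    b2 = sa * sa - npp / 2.0
    b = b1 - b2
    ts = (k * k / (6.0 * b ** 3) + k / b - b / 2.0) \
        - (k * k / (6.0 * a ** 3) + k / a - a / 2.0)
    tp1 = -2.0 * n2 * (b - a) / (npp ** 2)
    tp2 = -2.0 * n2 * npp * math.log(b / a) / (nm ** 2)
    tp3 = n2 * (1.0 / b - 1.0 / a) / 2.0
    tp4 = 16.0 * n2 ** 2 * (n2 ** 2 + 1.0) \
        * math.log((2.0 * npp * b - nm ** 2) / (2.0 * npp * a - nm ** 2)) \
        / (npp ** 3 * nm ** 2)
    tp5 = 16.0 * n2 ** 3 \
        * (1.0 / (2.0 * npp * b - nm ** 2) - 1.0 / (2.0 * npp * a - nm ** 2)) \
        / (npp ** 3)
    tp = tp1 + tp2 + tp3 + tp4 + tp5
    return (ts + tp) / (2.0 * sa * sa)


def prospect5_scalar(ni, cab, car, cbrown, cw, cm, n_refr, kab, kcar, kbrown,
                     kw, km, alpha=40.0):
    """Leaf reflectance/transmittance at one wavelength."""
    k = (cab * kab + car * kcar + cbrown * kbrown + cw * kw + cm * km) / ni
    if k <= 0.0:
        theta = 1.0
    else:
        theta = (1.0 - k) * math.exp(-k) + k * k * float(exp1(k))
        theta = min(max(theta, 0.0), 1.0)

    talf = tav_scalar(alpha, n_refr)
    ralf = 1.0 - talf
    t12 = tav_scalar(90.0, n_refr)
    r12 = 1.0 - t12
    t21 = t12 / (n_refr * n_refr)
    r21 = 1.0 - t21

    denom = 1.0 - r21 * r21 * theta * theta
    Ta = talf * theta * t21 / denom
    Ra = ralf + r21 * theta * Ta
    t = t12 * theta * t21 / denom
    r = r12 + r21 * theta * t

    if r + t >= 1.0:
        Tsub = t / (t + (1.0 - t) * (ni - 1.0))
        Rsub = 1.0 - Tsub
    else:
        D = math.sqrt((1.0 + r + t) * (1.0 + r - t) * (1.0 - r + t) * (1.0 - r - t))
        rq = r * r
        tq = t * t
        a_ = (1.0 + rq - tq + D) / (2.0 * r)
        b_ = (1.0 - rq + tq + D) / (2.0 * t)
        bNm1 = b_ ** (ni - 1.0)
        bN2 = bNm1 * bNm1
        a2 = a_ * a_
        denom = a2 * bN2 - 1.0
        Rsub = a_ * (bN2 - 1.0) / denom
        Tsub = bNm1 * (a2 - 1.0) / denom

    denom = 1.0 - Rsub * r
    tran = Ta * Tsub / denom
    refl = Ra + Ta * Rsub * t / denom
    return refl, tran


def campbell_scalar(alia_deg):
    """Ellipsoidal leaf-angle class frequencies for one mean angle."""
    rd = math.pi / 180.0
    excent = math.exp(-1.6184e-5 * alia_deg ** 3 + 2.1145e-3 * alia_deg ** 2
                      - 1.2390e-1 * alia_deg + 3.2491)
    freqs = []
    for lo, hi in CLASS_EDGES:
        tl1 = lo * rd
        tl2 = hi * rd
        x1 = excent / math.sqrt(1.0 + excent ** 2 * math.tan(tl1) ** 2)
        x2 = excent / math.sqrt(1.0 + excent ** 2 * math.tan(tl2) ** 2)
        if abs(excent - 1.0) < 1e-9:
            f = abs(math.cos(tl1) - math.cos(tl2))
        else:
            alpha = excent / math.sqrt(abs(1.0 - excent ** 2))
            alpha2 = alpha * alpha
            if excent > 1.0:
                alpx1 = math.sqrt(alpha2 + x1 * x1)
                alpx2 = math.sqrt(alpha2 + x2 * x2)
                f = abs((x1 * alpx1 + alpha2 * math.log(x1 + alpx1))
                        - (x2 * alpx2 + alpha2 * math.log(x2 + alpx2)))
            else:
                almx1 = math.sqrt(alpha2 - x1 * x1)
                almx2 = math.sqrt(alpha2 - x2 * x2)
                f = abs((x1 * almx1 + alpha2 * math.asin(x1 / alpha))
                        - (x2 * almx2 + alpha2 * math.asin(x2 / alpha)))
        freqs.append(f)
    total = sum(freqs)
    return [f / total for f in freqs]


def volscatt_scalar(tts, tto, psi, ttl):
    rd = math.pi / 180.0
    cts = math.cos(tts * rd)
    cto = math.cos(tto * rd)
    sts = math.sin(tts * rd)
    sto = math.sin(tto * rd)
    cospsi = math.cos(psi * rd)
    psir = abs(psi) * rd
    costl = math.cos(ttl * rd)
    sintl = math.sin(ttl * rd)
    cs = costl * cts
    co = costl * cto
    ss = sintl * sts
    so = sintl * sto

    cosbts = 5.0
    if abs(ss) > 1e-6:
        cosbts = -cs / ss
    cosbto = 5.0
    if abs(so) > 1e-6:
        cosbto = -co / so

    if abs(cosbts) < 1.0:
        bts = math.acos(cosbts)
        ds = ss
    else:
        bts = math.pi
        ds = cs
    chi_s = 2.0 / math.pi * ((bts - math.pi / 2.0) * cs + math.sin(bts) * ss)

    if abs(cosbto) < 1.0:
        bto = math.acos(cosbto)
        do_ = so
    else:
        if tto < 90.0:
            bto = math.pi
            do_ = co
        else:
            bto = 0.0
            do_ = -co
    chi_o = 2.0 / math.pi * ((bto - math.pi / 2.0) * co + math.sin(bto) * so)

    btran1 = abs(bts - bto)
    btran2 = math.pi - abs(bts + bto - math.pi)
    if psir <= btran1:
        bt1, bt2, bt3 = psir, btran1, btran2
    else:
        bt1 = btran1
        if psir <= btran2:
            bt2, bt3 = psir, btran2
        else:
            bt2, bt3 = btran2, psir

    t1 = 2.0 * cs * co + ss * so * cospsi
    t2 = 0.0
    if bt2 > 0.0:
        t2 = math.sin(bt2) * (2.0 * ds * do_ + ss * so * math.cos(bt1) * math.cos(bt3))
    denom = 2.0 * math.pi ** 2
    frho = max(((math.pi - bt2) * t1 + t2) / denom, 0.0)
    ftau = max((-bt2 * t1 + t2) / denom, 0.0)
    return chi_s, chi_o, frho, ftau


def _j1(k, m, t):
    d = (k - m) * t
    if abs(d) > 1e-3:
        return (math.exp(-m * t) - math.exp(-k * t)) / (k - m)
    return 0.5 * t * (math.exp(-k * t) + math.exp(-m * t)) * (1.0 - d * d / 12.0)


def _j2(k, m, t):
    return (1.0 - math.exp(-(k + m) * t)) / (k + m)


def foursail_scalar(rho, tau, rsoil, lai, alia, hspot, tts, tto, psi):
    """Canopy bidirectional (rso) and hemispherical-directional (rdo)
    reflectance at one wavelength."""
    if lai <= 0.0:
        return rsoil, rsoil
    rd = math.pi / 180.0
    cts = math.cos(tts * rd)
    cto = math.cos(tto * rd)
    tants = math.tan(tts * rd)
    tanto = math.tan(tto * rd)
    dso = math.sqrt(tants ** 2 + tanto ** 2
                    - 2.0 * tants * tanto * math.cos(psi * rd))

    lidf = campbell_scalar(alia)
    ks = ko = bf = sob = sof = 0.0
    for freq, ttl in zip(lidf, LITAB):
        chi_s, chi_o, frho, ftau = volscatt_scalar(tts, tto, psi, ttl)
        ks += freq * chi_s / cts
        ko += freq * chi_o / cto
        sob += freq * frho * math.pi / (cts * cto)
        sof += freq * ftau * math.pi / (cts * cto)
        bf += freq * math.cos(ttl * rd) ** 2

    sdb = 0.5 * (ks + bf)
    sdf = 0.5 * (ks - bf)
    dob = 0.5 * (ko + bf)
    dof = 0.5 * (ko - bf)
    ddb = 0.5 * (1.0 + bf)
    ddf = 0.5 * (1.0 - bf)

    sigb = ddb * rho + ddf * tau
    sigf = ddf * rho + ddb * tau
    att = 1.0 - sigf
    m2 = (att + sigb) * (att - sigb)
    m = math.sqrt(m2) if m2 > 0 else 0.0
    sb = sdb * rho + sdf * tau
    sf = sdf * rho + sdb * tau
    vb = dob * rho + dof * tau
    vf = dof * rho + dob * tau
    w = sob * rho + sof * tau

    e1 = math.exp(-m * lai)
    e2 = e1 * e1
    rinf = (att - m) / sigb
    rinf2 = rinf * rinf
    re = rinf * e1
    denom = 1.0 - rinf2 * e2

    J1ks = _j1(ks, m, lai)
    J2ks = _j2(ks, m, lai)
    J1ko = _j1(ko, m, lai)
    J2ko = _j2(ko, m, lai)

    Ps = (sf + sb * rinf) * J1ks
    Qs = (sf * rinf + sb) * J2ks
    Pv = (vf + vb * rinf) * J1ko
    Qv = (vf * rinf + vb) * J2ko

    rdd = rinf * (1.0 - e2) / denom
    tdd = (1.0 - rinf2) * e1 / denom
    tsd = (Ps - re * Qs) / denom
    rsd = (Qs - re * Ps) / denom
    tdo = (Pv - re * Qv) / denom
    rdo = (Qv - re * Pv) / denom

    tss = math.exp(-ks * lai)
    too = math.exp(-ko * lai)
    z = _j2(ks, ko, lai)
    g1 = (z - J1ks * too) / (ko + m)
    g2 = (z - J1ko * tss) / (ks + m)
    T1 = (vf * rinf + vb) * g1 * (sf + sb * rinf)
    T2 = (vf + vb * rinf) * g2 * (sf * rinf + sb)
    T3 = (rdo * Qs + tdo * Ps) * rinf
    rsod = (T1 + T2 - T3) / (1.0 - rinf2)

    if hspot > 0.0:
        alf = min((dso / hspot) * 2.0 / (ks + ko), 200.0)
    else:
        alf = 1e6
    if alf == 0.0:
        tsstoo = tss
        sumint = (1.0 - tss) / (ks * lai)
    else:
        fhot = lai * math.sqrt(ko * ks)
        x1 = y1 = 0.0
        f1 = 1.0
        fint = (1.0 - math.exp(-alf)) * 0.05
        sumint = 0.0
        for istep in range(1, 21):
            if istep < 20:
                x2 = -math.log(1.0 - istep * fint) / alf
            else:
                x2 = 1.0
            y2 = -(ko + ks) * lai * x2 + fhot * (1.0 - math.exp(-alf * x2)) / alf
            f2 = math.exp(y2)
            if abs(y2 - y1) > 1e-12:
                sumint += (f2 - f1) * (x2 - x1) / (y2 - y1)
            else:
                sumint += f1 * (x2 - x1)
            x1, y1, f1 = x2, y2, f2
        tsstoo = f1

    rsos = w * lai * sumint
    dn = 1.0 - rsoil * rdd
    rdot = rdo + tdd * rsoil * (tdo + too) / dn
    rsodt = rsod + ((tss + tsd) * tdo + (tsd + tss * rsoil * rdd) * too) * rsoil / dn
    rsost = rsos + tsstoo * rsoil
    rsot = rsost + rsodt
    return rsot, rdot
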