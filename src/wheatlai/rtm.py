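"""Forward canopy radiative transfer: PROSPECT-5 leaf optics coupled to the
4SAIL turbid-medium canopy bidirectional reflectance model.

PROSPECT treats the leaf as a stack of ``Ni`` absorbing plates with rough
surfaces; absorption is the linear mixture of pigment, water and dry-matter
contents weighted by their specific absorption coefficients.  4SAIL solves
the four-stream (direct/diffuse up/down) scattering problem for a turbid
layer of area ``LAI`` with an ellipsoidal leaf-angle distribution of mean
inclination ``ALIA``, over a Lambertian soil background, including the
hot-spot correlation correction of size parameter ``hspot``.

All kernels are vectorized over a batch axis so a 100,000-entry look-up
table is simulated in seconds; the public single-sample functions
(:func:`prospect_leaf`, :func:`sail_canopy`) wrap the batch kernels.

The observed top-of-canopy reflectance factor mixes the purely directional
term and the hemispherical-directional term with the diffuse sky fraction
``skyl``: R = (1 - skyl) * rso + skyl * rdo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import exp1

from .errors import DataError, ParameterDomainError
from .optics import DEFAULT_CAR, OpticalConstants

__all__ = [
    "LeafParams", "CanopyParams", "SoilParams", "Geometry",
    "LeafSpectra", "CanopySpectrum",
    "prospect_leaf", "prospect_batch", "soil_spectrum",
    "sail_canopy", "sail_batch",
]

_RD = np.pi / 180.0

# Leaf inclination classes of the SAIL discretization: eight 10-degree
# classes below 80 degrees, five 2-degree classes up to 90.
_LITAB = np.array([5., 15., 25., 35., 45., 55., 65., 75., 81., 83., 85., 87., 89.])
_TL_LO = np.array([0., 10., 20., 30., 40., 50., 60., 70., 80., 82., 84., 86., 88.])
_TL_HI = np.array([10., 20., 30., 40., 50., 60., 70., 80., 82., 84., 86., 88., 90.])


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class LeafParams:
    """PROSPECT-5 leaf inputs.

    ni: structure parameter (number of elementary plates, >= 1);
    cab: chlorophyll a+b (ug cm-2); cw: equivalent water thickness (cm);
    cm: dry matter (g cm-2); cbp: brown pigment (ug cm-2).
    """

    ni: float
    cab: float
    cw: float
    cm: float
    cbp: float = 0.0

    def __post_init__(self) -> None:
        if self.ni < 1.0:
            raise ParameterDomainError(f"ni must be >= 1, got {self.ni}")
        for field in ("cab", "cw", "cm", "cbp"):
            if getattr(self, field) < 0:
                raise ParameterDomainError(f"{field} must be >= 0, got {getattr(self, field)}")


@dataclass(frozen=True)
class CanopyParams:
    """SAIL canopy inputs: leaf area index, average leaf inclination angle
    (degrees) and hot-spot size parameter."""

    lai: float
    alia: float
    hspot: float

    def __post_init__(self) -> None:
        if self.lai < 0:
            raise ParameterDomainError(f"lai must be >= 0, got {self.lai}")
        if not 0.0 < self.alia < 90.0:
            raise ParameterDomainError(f"alia must be in (0, 90), got {self.alia}")
        if self.hspot <= 0:
            raise ParameterDomainError(f"hspot must be > 0, got {self.hspot}")


@dataclass(frozen=True)
class SoilParams:
    """Soil brightness scalar applied to the dry-soil reference spectrum."""

    psoil: float

    def __post_init__(self) -> None:
        if self.psoil < 0:
            raise ParameterDomainError(f"psoil must be >= 0, got {self.psoil}")


@dataclass(frozen=True)
class Geometry:
    """Sun/view geometry: sun zenith tts, view zenith tto, relative azimuth
    psi (degrees) and diffuse sky fraction skyl."""

    tts: float
    tto: float
    psi: float
    skyl: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.tts < 90.0:
            raise ParameterDomainError(f"tts must be in [0, 90), got {self.tts}")
        if not 0.0 <= self.tto < 90.0:
            raise ParameterDomainError(f"tto must be in [0, 90), got {self.tto}")
        if not -180.0 <= self.psi <= 180.0:
            raise ParameterDomainError(f"psi must be in [-180, 180], got {self.psi}")
        if not 0.0 <= self.skyl <= 1.0:
            raise ParameterDomainError(f"skyl must be in [0, 1], got {self.skyl}")


@dataclass(frozen=True)
class LeafSpectra:
    """Leaf directional-hemispherical reflectance and transmittance."""

    wl: np.ndarray
    reflectance: np.ndarray
    transmittance: np.ndarray


@dataclass(frozen=True)
class CanopySpectrum:
    """Directional canopy (or soil) reflectance factor per wavelength."""

    wl: np.ndarray
    reflectance: np.ndarray


# ---------------------------------------------------------------------------
# PROSPECT-5


def _tav(alpha_deg: float, nr: np.ndarray) -> np.ndarray:
    """Average transmissivity of a dielectric interface for isotropic light
    restricted to a cone of half-angle ``alpha_deg`` (Stern/Allen formula)."""
    n2 = nr ** 2
    npl = n2 + 1.0
    nm = n2 - 1.0
    a = (nr + 1.0) ** 2 / 2.0
    k = -((n2 - 1.0) ** 2) / 4.0
    sa = np.sin(alpha_deg * _RD)
    if alpha_deg != 90.0:
        b1 = np.sqrt((sa ** 2 - npl / 2.0) ** 2 + k)
    else:
        b1 = 0.0
    b2 = sa ** 2 - npl / 2.0
    b = b1 - b2
    b3 = b ** 3
    a3 = a ** 3
    ts = (k ** 2 / (6.0 * b3) + k / b - b / 2.0) - (k ** 2 / (6.0 * a3) + k / a - a / 2.0)
    tp1 = -2.0 * n2 * (b - a) / npl ** 2
    tp2 = -2.0 * n2 * npl * np.log(b / a) / nm ** 2
    tp3 = n2 * (1.0 / b - 1.0 / a) / 2.0
    tp4 = (16.0 * n2 ** 2 * (n2 ** 2 + 1.0)
           * np.log((2.0 * npl * b - nm ** 2) / (2.0 * npl * a - nm ** 2))
           / (npl ** 3 * nm ** 2))
    tp5 = (16.0 * n2 ** 3
           * (1.0 / (2.0 * npl * b - nm ** 2) - 1.0 / (2.0 * npl * a - nm ** 2))
           / npl ** 3)
    tp = tp1 + tp2 + tp3 + tp4 + tp5
    return (ts + tp) / (2.0 * sa ** 2)


def _plate_transmission(k: np.ndarray) -> np.ndarray:
    """Isotropic transmission through one absorbing plate of optical depth k."""
    t = np.ones_like(k)
    pos = k > 0
    kp = k[pos]
    t[pos] = (1.0 - kp) * np.exp(-kp) + kp ** 2 * exp1(kp)
    return np.clip(t, 0.0, 1.0)


def prospect_batch(
    params: np.ndarray,
    constants: OpticalConstants,
    car: float = DEFAULT_CAR,
    alpha: float = 40.0,
) -> tuple[np.ndarray, np.ndarray]:
    """PROSPECT-5 for a batch of leaves.

    Parameters
    ----------
    params : ndarray, shape (B, 5)
        Columns ni, cab, cw, cm, cbp.
    constants : OpticalConstants
    car : float
        Carotenoid content (ug cm-2), held constant across the batch.
    alpha : float
        Maximum incidence angle of the top-surface cone (degrees).

    Returns
    -------
    (reflectance, transmittance) : ndarrays of shape (B, n_wl)
    """
    params = np.atleast_2d(np.asarray(params, dtype=float))
    ni = params[:, 0:1]
    cab, cw, cm, cbp = (params[:, i:i + 1] for i in (1, 2, 3, 4))
    if np.any(ni < 1.0):
        raise ParameterDomainError("ni must be >= 1 for every batch member")
    if np.any(params[:, 1:] < 0):
        raise ParameterDomainError("cab/cw/cm/cbp must be >= 0 for every batch member")

    c = constants
    # total absorption per elementary plate
    k = (cab * c.k_cab + car * c.k_car + cbp * c.k_brown
         + cw * c.k_w + cm * c.k_m) / ni
    theta = _plate_transmission(k)

    # interface quantities depend only on the refractive index spectrum
    talf = _tav(alpha, c.n)
    ralf = 1.0 - talf
    t12 = _tav(90.0, c.n)
    r12 = 1.0 - t12
    t21 = t12 / c.n ** 2
    r21 = 1.0 - t21

    denom = 1.0 - (r21 * theta) ** 2
    Ta = talf * theta * t21 / denom
    Ra = ralf + r21 * theta * Ta
    t = t12 * theta * t21 / denom
    r = r12 + r21 * theta * t

    # Stokes extension of the single plate to ni - 1 additional layers
    rt_sum = r + t
    D2 = (1.0 + rt_sum) * (1.0 + r - t) * (1.0 - r + t) * (1.0 - rt_sum)
    D = np.sqrt(np.clip(D2, 0.0, None))
    rq = r ** 2
    tq = t ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        a_ = (1.0 + rq - tq + D) / (2.0 * r)
        b_ = (1.0 - rq + tq + D) / (2.0 * t)
        bNm1 = b_ ** (ni - 1.0)
        bN2 = bNm1 ** 2
        a2 = a_ ** 2
        denom2 = a2 * bN2 - 1.0
        Rsub = a_ * (bN2 - 1.0) / denom2
        Tsub = bNm1 * (a2 - 1.0) / denom2
    # conservative-scattering branch (r + t ~ 1): the doubling formula is 0/0
    cons = rt_sum >= 1.0 - 1e-12
    if np.any(cons):
        t_c = np.broadcast_to(t, cons.shape)[cons]
        ni_c = np.broadcast_to(ni, cons.shape)[cons]
        Tsub = np.where(cons, 0.0, Tsub)
        Rsub = np.where(cons, 0.0, Rsub)
        Tsub[cons] = t_c / (t_c + (1.0 - t_c) * (ni_c - 1.0))
        Rsub[cons] = 1.0 - Tsub[cons]

    denom3 = 1.0 - Rsub * r
    tran = Ta * Tsub / denom3
    refl = Ra + Ta * Rsub * t / denom3
    return np.clip(refl, 0.0, 1.0), np.clip(tran, 0.0, 1.0)


def prospect_leaf(leaf: LeafParams, constants: OpticalConstants,
                  car: float = DEFAULT_CAR) -> LeafSpectra:
    """Simulate leaf directional-hemispherical reflectance and transmittance."""
    r, t = prospect_batch(
        np.array([[leaf.ni, leaf.cab, leaf.cw, leaf.cm, leaf.cbp]]),
        constants, car=car,
    )
    return LeafSpectra(wl=constants.wl, reflectance=r[0], transmittance=t[0])


# ---------------------------------------------------------------------------
# soil


def soil_spectrum(soil: SoilParams, constants: OpticalConstants,
                  mode: str = "brightness") -> CanopySpectrum:
    """Soil background reflectance.

    mode="brightness" (default): psoil scales the dry-soil reference and the
    result is clipped to [0, 1]; this admits the brightness range up to 3.5
    used by the retrieval priors.  mode="drywet": the common convex mixture
    psoil*dry + (1-psoil)*wet, requiring psoil in [0, 1].
    """
    if mode == "brightness":
        refl = np.clip(soil.psoil * constants.soil_dry, 0.0, 1.0)
    elif mode == "drywet":
        if not 0.0 <= soil.psoil <= 1.0:
            raise ParameterDomainError("drywet mixing requires psoil in [0, 1]")
        refl = soil.psoil * constants.soil_dry + (1.0 - soil.psoil) * constants.soil_wet
    else:
        raise ParameterDomainError(f"unknown soil mode {mode!r}")
    return CanopySpectrum(wl=constants.wl, reflectance=refl)


# ---------------------------------------------------------------------------
# 4SAIL


def _campbell_lidf(alia: np.ndarray) -> np.ndarray:
    """Ellipsoidal (Campbell) leaf inclination distribution.

    Returns class frequencies over the 13 SAIL inclination classes for each
    mean leaf angle in ``alia`` (degrees); shape (B, 13).
    """
    alia = np.atleast_1d(np.asarray(alia, dtype=float))
    excent = np.exp(-1.6184e-5 * alia ** 3 + 2.1145e-3 * alia ** 2
                    - 1.2390e-1 * alia + 3.2491)[:, None]  # (B,1)
    tl1 = _TL_LO[None, :] * _RD
    tl2 = _TL_HI[None, :] * _RD
    x1 = excent / np.sqrt(1.0 + excent ** 2 * np.tan(tl1) ** 2)
    x2 = excent / np.sqrt(1.0 + excent ** 2 * np.tan(tl2) ** 2)

    alpha = excent / np.sqrt(np.abs(1.0 - excent ** 2))
    alpha2 = alpha ** 2
    # oblate (excent > 1) and prolate (excent < 1) closed forms
    with np.errstate(invalid="ignore"):
        alpx1 = np.sqrt(alpha2 + x1 ** 2)
        alpx2 = np.sqrt(alpha2 + x2 ** 2)
        freq_gt = np.abs((x1 * alpx1 + alpha2 * np.log(x1 + alpx1))
                         - (x2 * alpx2 + alpha2 * np.log(x2 + alpx2)))
        almx1 = np.sqrt(np.clip(alpha2 - x1 ** 2, 0.0, None))
        almx2 = np.sqrt(np.clip(alpha2 - x2 ** 2, 0.0, None))
        freq_lt = np.abs((x1 * almx1 + alpha2 * np.arcsin(np.clip(x1 / alpha, -1, 1)))
                         - (x2 * almx2 + alpha2 * np.arcsin(np.clip(x2 / alpha, -1, 1))))
    freq_sp = np.abs(np.cos(tl1) - np.cos(tl2)) * np.ones_like(excent)
    freq = np.where(np.isclose(excent, 1.0, atol=1e-9), freq_sp,
                    np.where(excent > 1.0, freq_gt, freq_lt))
    return freq / freq.sum(axis=1, keepdims=True)


def _volscatt(tts: float, tto: float, psi: float) -> tuple[np.ndarray, ...]:
    """Verhoef geometric factors for each leaf inclination class.

    Returns (chi_s, chi_o, frho, ftau), each of shape (13,): fractional
    cross-sections toward sun and observer, and the bidirectional
    reflectance/transmittance scattering factors of a single leaf class.
    """
    cts, cto = np.cos(tts * _RD), np.cos(tto * _RD)
    sts, sto = np.sin(tts * _RD), np.sin(tto * _RD)
    cospsi = np.cos(psi * _RD)
    psir = abs(psi) * _RD

    ttl = _LITAB * _RD
    costl, sintl = np.cos(ttl), np.sin(ttl)
    cs = costl * cts
    co = costl * cto
    ss = sintl * sts
    so = sintl * sto

    cosbts = np.where(np.abs(ss) > 1e-6, -cs / np.where(ss == 0, 1, ss), 5.0)
    cosbto = np.where(np.abs(so) > 1e-6, -co / np.where(so == 0, 1, so), 5.0)

    in_s = np.abs(cosbts) < 1.0
    bts = np.where(in_s, np.arccos(np.clip(cosbts, -1, 1)), np.pi)
    ds = np.where(in_s, ss, cs)
    chi_s = 2.0 / np.pi * ((bts - np.pi / 2.0) * cs + np.sin(bts) * ss)

    in_o = np.abs(cosbto) < 1.0
    bto = np.where(in_o, np.arccos(np.clip(cosbto, -1, 1)),
                   np.pi if tto < 90.0 else 0.0)
    do_ = np.where(in_o, so, co if tto < 90.0 else -co)
    chi_o = 2.0 / np.pi * ((bto - np.pi / 2.0) * co + np.sin(bto) * so)

    btran1 = np.abs(bts - bto)
    btran2 = np.pi - np.abs(bts + bto - np.pi)
    bt1 = np.where(psir <= btran1, psir, btran1)
    bt2 = np.where(psir <= btran1, btran1,
                   np.where(psir <= btran2, psir, btran2))
    bt3 = np.where(psir <= btran1, btran2,
                   np.where(psir <= btran2, btran2, psir))

    t1 = 2.0 * cs * co + ss * so * cospsi
    t2 = np.where(bt2 > 0.0,
                  np.sin(bt2) * (2.0 * ds * do_ + ss * so * np.cos(bt1) * np.cos(bt3)),
                  0.0)
    denom = 2.0 * np.pi ** 2
    frho = np.clip(((np.pi - bt2) * t1 + t2) / denom, 0.0, None)
    ftau = np.clip((-bt2 * t1 + t2) / denom, 0.0, None)
    return chi_s, chi_o, frho, ftau


def _hotspot_integral(ks, ko, lai, hspot, dso):
    """Bidirectional gap-probability integral along the canopy depth.

    Returns (tsstoo, sumint): the joint sun-observer gap fraction and the
    depth integral that scales single-scattering toward the observer.
    Vectorized over the batch; 20-step exponential quadrature in depth.
    """
    ks = np.asarray(ks, float)
    B = ks.shape[0]
    alf = np.full(B, 1e6)
    hp = np.asarray(hspot, float)
    pos = hp > 0
    alf[pos] = np.minimum((dso / hp[pos]) * 2.0 / (ks[pos] + ko[pos]), 200.0)

    tsstoo = np.empty(B)
    sumint = np.empty(B)

    zero = alf == 0.0  # exact hot-spot geometry (dso == 0)
    if np.any(zero):
        tss_z = np.exp(-ks[zero] * lai[zero])
        tsstoo[zero] = tss_z
        sumint[zero] = (1.0 - tss_z) / (ks[zero] * lai[zero])

    nz = ~zero
    if np.any(nz):
        a = alf[nz]
        ksn, kon, lain = ks[nz], ko[nz], lai[nz]
        fhot = lain * np.sqrt(ksn * kon)
        x1 = np.zeros_like(a)
        y1 = np.zeros_like(a)
        f1 = np.ones_like(a)
        fint = (1.0 - np.exp(-a)) * 0.05
        s = np.zeros_like(a)
        for istep in range(1, 21):
            if istep < 20:
                x2 = -np.log(1.0 - istep * fint) / a
            else:
                x2 = np.ones_like(a)
            y2 = -(kon + ksn) * lain * x2 + fhot * (1.0 - np.exp(-a * x2)) / a
            f2 = np.exp(y2)
            dy = y2 - y1
            s += np.where(np.abs(dy) > 1e-12, (f2 - f1) * (x2 - x1) / dy, f1 * (x2 - x1))
            x1, y1, f1 = x2, y2, f2
        tsstoo[nz] = f1
        sumint[nz] = s
    return tsstoo, sumint


def _jfunc1(k, m, lai):
    """(exp(-m L) - exp(-k L)) / (k - m) with a series fallback near k = m."""
    d = (k - m) * lai
    safe = np.where(np.abs(d) > 1e-3,
                    np.where(np.abs(k - m) > 0, k - m, 1.0), 1.0)
    main = (np.exp(-m * lai) - np.exp(-k * lai)) / safe
    series = 0.5 * lai * (np.exp(-k * lai) + np.exp(-m * lai)) * (1.0 - d * d / 12.0)
    return np.where(np.abs(d) > 1e-3, main, series)


def _jfunc2(k, m, lai):
    return (1.0 - np.exp(-(k + m) * lai)) / (k + m)


def sail_batch(
    rho: np.ndarray,
    tau: np.ndarray,
    rsoil: np.ndarray,
    lai: np.ndarray,
    alia: np.ndarray,
    hspot: np.ndarray,
    geom: Geometry,
) -> tuple[np.ndarray, np.ndarray]:
    """4SAIL for a batch of canopies sharing one sun/view geometry.

    Parameters
    ----------
    rho, tau : ndarray (B, W)
        Leaf reflectance and transmittance spectra.
    rsoil : ndarray (B, W) or (W,)
        Soil background reflectance.
    lai, alia, hspot : ndarray (B,)
    geom : Geometry

    Returns
    -------
    (rso, rdo) : ndarrays (B, W)
        Bidirectional and hemispherical-directional top-of-canopy
        reflectance factors.  Mix with the diffuse fraction to obtain the
        observed reflectance: (1-skyl)*rso + skyl*rdo.
    """
    rho = np.atleast_2d(np.asarray(rho, float))
    tau = np.atleast_2d(np.asarray(tau, float))
    if rho.shape != tau.shape:
        raise DataError("leaf reflectance/transmittance grids differ")
    B, W = rho.shape
    rsoil = np.broadcast_to(np.asarray(rsoil, float), (B, W))
    lai = np.broadcast_to(np.asarray(lai, float), (B,)).astype(float)
    alia = np.broadcast_to(np.asarray(alia, float), (B,))
    hspot = np.broadcast_to(np.asarray(hspot, float), (B,))
    if np.any((alia <= 0) | (alia >= 90)):
        raise ParameterDomainError("alia must be in (0, 90) for every batch member")
    if np.any(lai < 0):
        raise ParameterDomainError("lai must be >= 0")

    tts, tto, psi = geom.tts, geom.tto, geom.psi
    cts, cto = np.cos(tts * _RD), np.cos(tto * _RD)
    ctscto = cts * cto
    tants, tanto = np.tan(tts * _RD), np.tan(tto * _RD)
    dso = np.sqrt(tants ** 2 + tanto ** 2 - 2.0 * tants * tanto * np.cos(psi * _RD))

    chi_s, chi_o, frho, ftau = _volscatt(tts, tto, psi)
    ksli = chi_s / cts
    koli = chi_o / cto
    sobli = frho * np.pi / ctscto
    sofli = ftau * np.pi / ctscto
    bfli = np.cos(_LITAB * _RD) ** 2

    lidf = _campbell_lidf(alia)                      # (B, 13)
    ks = lidf @ ksli                                 # (B,)
    ko = lidf @ koli
    bf = lidf @ bfli
    sob = lidf @ sobli
    sof = lidf @ sofli

    col = lambda v: v[:, None]                       # (B,) -> (B,1)
    sdb, sdf = 0.5 * (ks + bf), 0.5 * (ks - bf)
    dob, dof = 0.5 * (ko + bf), 0.5 * (ko - bf)
    ddb, ddf = 0.5 * (1.0 + bf), 0.5 * (1.0 - bf)

    sigb = col(ddb) * rho + col(ddf) * tau
    sigb = np.where(np.abs(sigb) < 1e-36, 1e-36, sigb)
    sigf = col(ddf) * rho + col(ddb) * tau
    att = 1.0 - sigf
    m = np.sqrt(np.clip((att + sigb) * (att - sigb), 0.0, None))
    sb = col(sdb) * rho + col(sdf) * tau
    sf = col(sdf) * rho + col(sdb) * tau
    vb = col(dob) * rho + col(dof) * tau
    vf = col(dof) * rho + col(dob) * tau
    w = col(sob) * rho + col(sof) * tau

    # transparent-canopy limit handled exactly
    thin = lai <= 1e-9
    laiw = np.where(thin, 1.0, lai)[:, None]         # safe placeholder depth
    ksw, kow = col(ks), col(ko)

    e1 = np.exp(-m * laiw)
    e2 = e1 ** 2
    rinf = (att - m) / sigb
    rinf2 = rinf ** 2
    re = rinf * e1
    denom = 1.0 - rinf2 * e2

    J1ks = _jfunc1(ksw, m, laiw)
    J2ks = _jfunc2(ksw, m, laiw)
    J1ko = _jfunc1(kow, m, laiw)
    J2ko = _jfunc2(kow, m, laiw)

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

    tss = np.exp(-ksw * laiw)
    too = np.exp(-kow * laiw)
    z = _jfunc2(ksw, kow, laiw)
    g1 = (z - J1ks * too) / (kow + m)
    g2 = (z - J1ko * tss) / (ksw + m)
    Tv1 = (vf * rinf + vb) * g1
    Tv2 = (vf + vb * rinf) * g2
    T1 = Tv1 * (sf + sb * rinf)
    T2 = Tv2 * (sf * rinf + sb)
    T3 = (rdo * Qs + tdo * Ps) * rinf
    rsod = (T1 + T2 - T3) / (1.0 - rinf2)

    tsstoo_b, sumint_b = _hotspot_integral(ks, ko, np.where(thin, 1.0, lai),
                                           hspot, dso)
    rsos = w * np.where(thin, 0.0, lai)[:, None] * sumint_b[:, None]
    tsstoo = tsstoo_b[:, None]

    if np.any(thin):
        tcol = thin[:, None]
        zero_like = np.zeros_like(rdd)
        one_like = np.ones_like(rdd)
        rdd = np.where(tcol, zero_like, rdd)
        rsd = np.where(tcol, zero_like, rsd)
        rdo = np.where(tcol, zero_like, rdo)
        rsod = np.where(tcol, zero_like, rsod)
        rsos = np.where(tcol, zero_like, rsos)
        tdd = np.where(tcol, one_like, tdd)
        tsd = np.where(tcol, zero_like, tsd)
        tdo = np.where(tcol, zero_like, tdo)
        tss = np.where(tcol, one_like, tss)
        too = np.where(tcol, one_like, too)
        tsstoo = np.where(tcol, one_like, tsstoo)

    dn = 1.0 - rsoil * rdd
    rdot = rdo + tdd * rsoil * (tdo + too) / dn
    rsodt = rsod + ((tss + tsd) * tdo + (tsd + tss * rsoil * rdd) * too) * rsoil / dn
    rsost = rsos + tsstoo * rsoil
    rsot = rsost + rsodt
    return rsot, rdot


def sail_canopy(
    leaf: LeafSpectra,
    canopy: CanopyParams,
    soil: CanopySpectrum,
    geom: Geometry,
) -> CanopySpectrum:
    """Top-of-canopy reflectance factor observed under diffuse fraction skyl."""
    if leaf.wl.shape != soil.wl.shape or not np.allclose(leaf.wl, soil.wl):
        raise DataError("leaf and soil spectra are on different wavelength grids")
    rso, rdo = sail_batch(
        leaf.reflectance[None, :], leaf.transmittance[None, :],
        soil.reflectance[None, :],
        np.array([canopy.lai]), np.array([canopy.alia]), np.array([canopy.hspot]),
        geom,
    )
    # written so the bare-soil limit (rso == rdo == rsoil) is bit-exact
    refl = rso[0] + geom.skyl * (rdo[0] - rso[0])
    return CanopySpectrum(wl=leaf.wl, reflectance=refl)
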