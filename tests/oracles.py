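"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's own algorithms: gamma by exhaustive
search over a dense grid without a search window, the pristine-peak model by
direct adaptive quadrature of the singular convolution integral, spectrum
recovery by constrained grid search, and the paired statistics by textbook
formulas.
"""
from __future__ import annotations

import numpy as np
from scipy import integrate
from scipy.interpolate import RegularGridInterpolator


def brute_gamma_1d(z_ref, d_ref, z_ev, d_ev, dta, dd_abs, fine_step):
    """Exhaustive 1-D gamma: evaluated resampled to a full fine grid, no window."""
    zf = np.arange(z_ev[0], z_ev[-1] + fine_step / 2, fine_step)
    df = np.interp(zf, z_ev, d_ev)
    out = np.empty(len(z_ref))
    for i, (z, d) in enumerate(zip(z_ref, d_ref)):
        g2 = ((zf - z) / dta) ** 2 + ((df - d) / dd_abs) ** 2
        out[i] = np.sqrt(g2.min())
    return out


def brute_gamma_2d(ref_xy, ref_dose, ev_x, ev_y, ev_dose, dta, dd_abs, fine_step):
    """Exhaustive 2-D gamma over a dense bilinear resampling of the evaluated plane."""
    xf = np.arange(ev_x[0], ev_x[-1] + fine_step / 2, fine_step)
    yf = np.arange(ev_y[0], ev_y[-1] + fine_step / 2, fine_step)
    interp = RegularGridInterpolator((ev_y, ev_x), ev_dose, method="linear")
    gy, gx = np.meshgrid(yf, xf, indexing="ij")
    df = interp(np.column_stack([gy.ravel(), gx.ravel()])).reshape(gy.shape)
    out = np.empty(len(ref_xy))
    for i, ((x, y), d) in enumerate(zip(ref_xy, ref_dose)):
        g2 = ((gx - x) ** 2 + (gy - y) ** 2) / dta**2 + ((df - d) / dd_abs) ** 2
        out[i] = np.sqrt(g2.min())
    return out


def quad_bragg_dose(z_mm, range_cm, k=0.012, m=0.935, p=1.77):
    """Pristine-peak dose at depths z by direct quadrature of the convolution.

    D(z) = integral_0^R (R-u)^(1/p-1) * exp(-(z-u)^2 / (2 sigma^2)) du,
    evaluated per depth with the singular endpoint handled by substitution
    t = (R-u)^(1/p).
    """
    a = 1.0 / p - 1.0
    r = range_cm * 10.0
    sigma = k * range_cm**m * 10.0

    def dose_at(z):
        # substitute t = (R-u)**(1/p): integrand becomes p * exp(...) dt, smooth
        def f(t):
            u = r - t**p
            return p * np.exp(-0.5 * ((z - u) / sigma) ** 2)

        val, _ = integrate.quad(f, 0.0, r ** (1.0 / p), limit=200)
        return val

    return np.array([dose_at(z) for z in np.atleast_1d(z_mm)])


def quad_bragg_r80(range_cm, **kw):
    """Distal 80% depth of the quadrature peak, bisected to 1e-4 mm."""
    r = range_cm * 10.0
    sigma = kw.get("k", 0.012) * range_cm ** kw.get("m", 0.935) * 10.0
    z = np.linspace(r - 6 * sigma, r + 4 * sigma, 400)
    d = quad_bragg_dose(z, range_cm, **kw)
    peak = d.max()
    i = d.argmax()
    lo, hi = z[i], z[-1]
    f = lambda zz: quad_bragg_dose([zz], range_cm, **kw)[0] - 0.8 * peak
    while hi - lo > 1e-4:
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def grid_search_two_weights(measured, b_i, b_j, n=201):
    """Best (w_i, w_j) >= 0 mixing two basis members, by exhaustive scan.

    Scans the mixing fraction and solves the optimal overall scale in closed
    form for each candidate.
    """
    best = (np.inf, 0.0, 0.0)
    for f in np.linspace(0.0, 1.0, n):
        mix = f * b_i + (1 - f) * b_j
        scale = float(measured @ mix / (mix @ mix))
        resid = float(np.linalg.norm(measured - scale * mix))
        if resid < best[0]:
            best = (resid, scale * f, scale * (1 - f))
    return best[1], best[2]


def textbook_paired_t(x, y):
    """Paired t statistic and two-sided p from the direct formula."""
    from scipy.stats import t as tdist

    d = np.asarray(x, float) - np.asarray(y, float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = 2.0 * tdist.sf(abs(t), n - 1)
    return t, p


def textbook_pearson(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
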