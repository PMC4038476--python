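"""Independent oracles used by the tests.

These deliberately avoid the package's own code paths: the step response is
re-derived by numerical ODE integration of the equivalent circuit, and the
passive parameters by a brute-force two-exponential nonlinear least-squares
fit of the whole response.
"""

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit


def ode_step_voltage(params, protocol, t_eval):
    """Integrate the electrode+membrane RC pair with solve_ivp.

    State: (v_e, v_m) voltage drops across the electrode residual and the
    membrane, each first-order toward I*R with its own time constant.
    """
    tau_e = max(params.tau_e * 1e-3, 1e-9)
    tau_m = params.tau_m * 1e-3
    onset, offset = protocol.onset_s, protocol.onset_s + protocol.duration_s

    def current(t):
        return protocol.amplitude_na if onset <= t < offset else 0.0

    def rhs(t, y):
        i = current(t)
        return [
            (i * params.bridge_error - y[0]) / tau_e,
            (i * params.R_in - y[1]) / tau_m,
        ]

    sol = solve_ivp(
        rhs, (0.0, t_eval[-1]), [0.0, 0.0], t_eval=t_eval,
        max_step=min(tau_e / 4.0, 1e-4), rtol=1e-9, atol=1e-12,
    )
    return params.E_rest + sol.y[0] + sol.y[1]


def _biexp(t, v0, a_e, te, a_m, tm):
    return v0 + a_e * (1 - np.exp(-t / te)) + a_m * (1 - np.exp(-t / tm))


def biexp_fit(trace, protocol=None):
    """Two-exponential NLS over the whole step segment.

    Returns (tau_e_ms, tau_m_ms, r_a_mohm, r_in_mohm) with the amplitudes
    converted to resistances via the command amplitude.
    """
    protocol = protocol or trace.protocol
    amp = protocol.amplitude_na
    i0 = int(round(protocol.onset_s * trace.sampling_rate))
    i1 = int(round((protocol.onset_s + protocol.duration_s) * trace.sampling_rate))
    t = np.arange(i1 - i0) / trace.sampling_rate
    v = trace.voltage[i0:i1]
    p0 = [v[0], 0.1 * (v[-1] - v[0]), 2e-4, 0.9 * (v[-1] - v[0]), 1e-2]
    with np.errstate(over="ignore"):
        popt, _ = curve_fit(_biexp, t, v, p0=p0, maxfev=20000)
    v0, a_e, te, a_m, tm = popt
    # identify the electrode with the faster component
    if te > tm:
        a_e, te, a_m, tm = a_m, tm, a_e, te
    return te * 1e3, tm * 1e3, a_e / amp, a_m / amp
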