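"""Independent reference implementations used as test oracles.

These deliberately avoid the package's integrator and surface-area algebra:
the Euler oracle tracks per-particle geometry explicitly (particle count from
the deposited dose, per-sphere mass -> diameter -> area) and steps the four
stocks with a naive forward-Euler loop written directly from the kinetic
laws, so agreement with the package is a genuine cross-check.
"""

import math


def euler_oracle(*, Cs, IDR, d0, rho, Pexp, hexp, hm, S, Vd, Vr, Q, M0,
                 particles=True, well_stirred=True, t_end=60.0, dt=1e-3):
    """Integrate the four-stock system by naive forward Euler.

    Returns ``(ms, md, mr, mc)`` at ``t_end`` (g). All arguments in
    cm-g-min units.
    """
    k = IDR / Cs
    n_particles = 6.0 * M0 / (math.pi * d0 ** 3 * rho)
    h_t = Vd / S
    ms, md = (M0, 0.0) if particles else (0.0, M0)
    mr = mc = 0.0
    n_steps = int(round(t_end / dt))
    for _ in range(n_steps):
        C = md / Vd
        Cp = mr / Vr
        if particles and ms > 0.0:
            m_per_particle = ms / n_particles
            diameter = (6.0 * m_per_particle / (math.pi * rho)) ** (1.0 / 3.0)
            area = n_particles * math.pi * diameter ** 2
            dissolution = max(0.0, k * area * (Cs - C))
        else:
            dissolution = 0.0
        if well_stirred:
            P = Pexp * hexp / hm
        else:
            f_d = (mr + mc) / M0
            P = Pexp * hexp / (hm + f_d * h_t)
        permeation = P * S * (C - Cp)
        collection = Cp * Q
        ms -= dt * dissolution
        md += dt * (dissolution - permeation)
        mr += dt * (permeation - collection)
        mc += dt * collection
        if ms < 0.0:
            md += ms
            ms = 0.0
        if md < 0.0:
            mr += md
            md = 0.0
        if mr < 0.0:
            mc += mr
            mr = 0.0
    return ms, md, mr, mc


def brute_force_powder_area(M_t, M0, d0, rho):
    """Total powder area by explicit per-sphere bookkeeping."""
    n_particles = 6.0 * M0 / (math.pi * d0 ** 3 * rho)
    m_per_particle = M_t / n_particles
    diameter = (6.0 * m_per_particle / (math.pi * rho)) ** (1.0 / 3.0)
    return n_particles * math.pi * diameter ** 2


def sink_donor_mass(M0, Pexp, S, Vd, t):
    """Closed-form donor mass for a pre-dissolved dose draining into a sink."""
    return M0 * math.exp(-Pexp * S * t / Vd)
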