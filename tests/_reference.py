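"""Independent second transcription of the model equations.

Used as a two-implementor oracle: this file re-derives the right-hand
side directly from the published equation forms, written term by term
and structured differently from the package implementation, and must
never import from ``mitoswitch.model``'s kinetics code.
"""

import numpy as np


def rhs_reference(y, p):
    """Hand-coded reference derivative of the six state variables."""
    MPF = y[0]
    Cdc25 = y[1]
    Wee1 = y[2]
    Gwl = y[3]
    ENSAPt = y[4]
    PP2 = y[5]

    # inhibitor-corrected active fractions (reversible drug binding)
    MPFa = MPF / (1 + p.RO)
    PP2a = PP2 / (1 + p.OA)

    # effective Tyr15 modification rates, linear in the regulators
    k25 = p.k25_p * (p.Cdc25T - Cdc25) + p.k25_pp * Cdc25
    kwee = p.kwee_p * (p.Wee1T - Wee1) + p.kwee_pp * Wee1

    d = np.zeros(6)
    d[0] = k25 * (p.CycT - MPF) - kwee * MPF
    d[1] = p.Va25 * MPFa * (p.Cdc25T - Cdc25) - p.Vi25 * PP2a * Cdc25
    d[2] = p.Vawee * PP2a * (p.Wee1T - Wee1) - p.Viwee * MPFa * Wee1
    # three candidate Gwl-phosphatase routes summed in the decay term
    gwl_decay = p.kigwl_p
    gwl_decay = gwl_decay + p.kigwl_pp * p.PP2T / (1 + p.OA)
    gwl_decay = gwl_decay + p.kigwl * PP2a
    d[3] = p.kagwl * MPFa * (p.GwlT - Gwl) - gwl_decay * Gwl
    d[4] = p.kaensa * Gwl * (p.ENSAT - ENSAPt) - p.kiensa * ENSAPt
    free_ensap = ENSAPt - (p.PP2T - PP2)
    d[5] = -p.kas * free_ensap * PP2 + (p.kdis + p.kiensa) * (p.PP2T - PP2)
    return d


def euler_reference(y0, p, horizon, dt=1e-5):
    """Fixed-step explicit Euler integration as a solver oracle."""
    y = np.array(y0, dtype=float)
    n = int(round(horizon / dt))
    for _ in range(n):
        y += dt * rhs_reference(y, p)
    return y
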