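"""Independent reference implementations used only by the test suite.

These are deliberately written as plain scalar Python (math module, explicit
step-by-step formulas) so they share no code path with the vectorized
package implementations they check.
"""

import math


def ciede2000_reference(lab1, lab2):
    """Term-by-term scalar transcription of the CIEDE2000 formula.

    Follows the published formulation with kL = kC = kH = 1, including the
    G chroma correction, piecewise mean-hue rules and the rotation term.
    """
    L1, a1, b1 = lab1
    L2, a2, b2 = lab2

    C1 = math.sqrt(a1 * a1 + b1 * b1)
    C2 = math.sqrt(a2 * a2 + b2 * b2)
    C_mean = (C1 + C2) / 2.0
    G = 0.5 * (1.0 - math.sqrt(C_mean**7 / (C_mean**7 + 25.0**7)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = math.sqrt(a1p * a1p + b1 * b1)
    C2p = math.sqrt(a2p * a2p + b2 * b2)

    def hue(ap, b):
        if ap == 0.0 and b == 0.0:
            return 0.0
        h = math.degrees(math.atan2(b, ap))
        return h + 360.0 if h < 0.0 else h

    h1p = hue(a1p, b1)
    h2p = hue(a2p, b2)

    dLp = L2 - L1
    dCp = C2p - C1p

    if C1p * C2p == 0.0:
        dhp = 0.0
    else:
        diff = h2p - h1p
        if abs(diff) <= 180.0:
            dhp = diff
        elif diff > 180.0:
            dhp = diff - 360.0
        else:
            dhp = diff + 360.0
    dHp = 2.0 * math.sqrt(C1p * C2p) * math.sin(math.radians(dhp) / 2.0)

    Lp_mean = (L1 + L2) / 2.0
    Cp_mean = (C1p + C2p) / 2.0
    if C1p * C2p == 0.0:
        hp_mean = h1p + h2p
    elif abs(h1p - h2p) <= 180.0:
        hp_mean = (h1p + h2p) / 2.0
    elif h1p + h2p < 360.0:
        hp_mean = (h1p + h2p + 360.0) / 2.0
    else:
        hp_mean = (h1p + h2p - 360.0) / 2.0

    T = (
        1.0
        - 0.17 * math.cos(math.radians(hp_mean - 30.0))
        + 0.24 * math.cos(math.radians(2.0 * hp_mean))
        + 0.32 * math.cos(math.radians(3.0 * hp_mean + 6.0))
        - 0.20 * math.cos(math.radians(4.0 * hp_mean - 63.0))
    )
    d_theta = 30.0 * math.exp(-(((hp_mean - 275.0) / 25.0) ** 2))
    R_C = 2.0 * math.sqrt(Cp_mean**7 / (Cp_mean**7 + 25.0**7))
    S_L = 1.0 + (0.015 * (Lp_mean - 50.0) ** 2) / math.sqrt(20.0 + (Lp_mean - 50.0) ** 2)
    S_C = 1.0 + 0.045 * Cp_mean
    S_H = 1.0 + 0.015 * Cp_mean * T
    R_T = -math.sin(math.radians(2.0 * d_theta)) * R_C

    term_L = dLp / S_L
    term_C = dCp / S_C
    term_H = dHp / S_H
    return math.sqrt(
        term_L * term_L + term_C * term_C + term_H * term_H + R_T * term_C * term_H
    )


def srgb_decode_scalar(v):
    """One-line piecewise sRGB decoding for a single channel in [0, 1]."""
    return v / 12.92 if v <= 0.04045 else ((v + 0.055) / 1.055) ** 2.4


def spectrum_to_xyz_scalar(reflectance, power, xbar, ybar, zbar):
    """Plain-loop Riemann-sum tristimulus with luminance normalization."""
    denom = sum(e * y for e, y in zip(power, ybar))
    k = 100.0 / denom
    X = k * sum(r * e * x for r, e, x in zip(reflectance, power, xbar))
    Y = k * sum(r * e * y for r, e, y in zip(reflectance, power, ybar))
    Z = k * sum(r * e * z for r, e, z in zip(reflectance, power, zbar))
    return X, Y, Z
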