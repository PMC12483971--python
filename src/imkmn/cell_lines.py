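"""Published microdosimetric-kinetic parameter sets for reference cell lines.

Values (posterior mean +/- SD where reported) for four lines commonly used in
LET- and dose-rate-dependence studies: human salivary gland tumour (HSG),
murine squamous cell carcinoma (SCC VII), normal human lung fibroblast
(WI-38) and human prostate cancer (DU145).  The pooled micronucleus-formation
probability h = 0.275 +/- 0.00618 was obtained from a through-origin fit of
MN per binucleated cell against -ln(survival) across many cell lines; the
per-line values below it span roughly 0.196-0.365.

These sets are reference inputs for predictions and for generating synthetic
datasets; absolute h values are assay-protocol dependent and should be
re-determined for any new scoring protocol.
"""

from __future__ import annotations

from .core_model import CellParameters

__all__ = [
    "HSG",
    "SCC",
    "WI38",
    "DU145",
    "POOLED_H",
    "POOLED_H_SD",
    "PARAMETER_SD",
    "PER_LINE_H",
    "REFERENCE_LINES",
]

#: Pooled MN-formation probability (dimensionless) and its posterior SD.
POOLED_H = 0.275
POOLED_H_SD = 6.18e-3

HSG = CellParameters(
    alpha0=0.150, beta0=4.67e-2, a_plus_c=2.19, r_d=0.42, h_mn=POOLED_H, label="HSG"
)
SCC = CellParameters(
    alpha0=8.25e-2, beta0=2.98e-2, a_plus_c=2.19, r_d=0.42, h_mn=POOLED_H, label="SCC"
)
WI38 = CellParameters(
    alpha0=0.590, beta0=1.63e-2, a_plus_c=0.371, r_d=0.50, h_mn=POOLED_H, label="WI-38"
)
DU145 = CellParameters(
    alpha0=7.74e-2, beta0=3.80e-2, a_plus_c=2.10, r_d=0.50, h_mn=POOLED_H, label="DU145"
)

#: Reported posterior SDs of (alpha0, beta0, a_plus_c) per line.
PARAMETER_SD = {
    "HSG": {"alpha0": 6.87e-2, "beta0": 7.21e-3, "a_plus_c": 4.00e-1},
    "SCC": {"alpha0": 4.34e-2, "beta0": 3.39e-3, "a_plus_c": 3.92e-1},
    "WI-38": {"alpha0": 1.07e-1, "beta0": 1.32e-2, "a_plus_c": 3.84e-2},
    "DU145": {"alpha0": 3.64e-2, "beta0": 4.98e-3, "a_plus_c": 9.11e-1},
}

#: Per-cell-line MN-formation probability (mean, SD).
PER_LINE_H = {
    "CHO": (3.65e-1, 3.17e-2),
    "HSG": (2.45e-1, 8.68e-3),
    "U2OS": (2.61e-1, 3.87e-2),
    "MCF-12A": (2.29e-1, 3.72e-2),
    "M5": (1.96e-1, 4.94e-2),
    "V79": (1.97e-1, 5.70e-2),
    "SCC VII": (2.81e-1, 7.47e-3),
}

#: MN-side parameter set fitted directly to HSG micronucleus dose-response
#: data: (alpha_m0 [Gy^-1], beta_m0 [Gy^-2], a+c [h^-1], r_d [um]).
HSG_MN_FIT = {
    "alpha_m0": 3.75e-2,
    "beta_m0": 1.13e-2,
    "a_plus_c": 2.19,
    "r_d": 0.40,
}
HSG_MN_FIT_SD = {"alpha_m0": 3.28e-2, "beta_m0": 3.48e-3, "a_plus_c": 3.91e-1}

REFERENCE_LINES = {p.label: p for p in (HSG, SCC, WI38, DU145)}
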