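"""Reference parameter set for a commercial turkey female line.

These constants describe the genetic architecture of weekly egg production
over a 24-week lay trajectory (counted from each hen's first egg) in a
commercial turkey dam line: the (co)variance matrices of order-3 normalized
Legendre regression coefficients for additive genetic and permanent
environmental effects, four-period heterogeneous residual variances, and the
weekly phenotypic means/SDs of the trait.  They are used throughout the
package as the default generating values of the synthetic-data module and as
the worked-example inputs of the trajectory-parameter calculations.
"""

from __future__ import annotations

import numpy as np

#: Number of weekly records per hen, counted from the week of first egg.
N_WEEKS = 24

#: Order of the Legendre polynomial regressions (order 3 = 4 covariates).
DEFAULT_ORDER = 3

#: Posterior-mean (co)variance matrix of the four additive genetic
#: random-regression coefficients (normalized Legendre basis, order 3).
#: Printed at two decimals; slightly indefinite as a consequence
#: (min eigenvalue ~ -0.005), see :func:`eggtraj.covfun.nearest_pd`.
ADDITIVE_COEFF_COV = np.array(
    [
        [0.62, 0.06, -0.08, -0.01],
        [0.06, 0.04, -0.02, -0.02],
        [-0.08, -0.02, 0.02, 0.00],
        [-0.01, -0.02, 0.00, 0.01],
    ]
)

#: Posterior-mean (co)variance matrix of the four permanent environmental
#: random-regression coefficients.
PE_COEFF_COV = np.array(
    [
        [0.73, -0.03, -0.12, 0.04],
        [-0.03, 0.18, -0.01, -0.06],
        [-0.12, -0.01, 0.09, -0.01],
        [0.04, -0.06, -0.01, 0.05],
    ]
)

#: Heterogeneous residual variances by period of lay: (week_lo, week_hi, var).
#: These period boundaries reproduce the published weekly heritabilities.
RESIDUAL_PERIODS = [
    (1, 4, 1.33),
    (5, 12, 1.38),
    (13, 17, 1.21),
    (18, 24, 1.10),
]

#: Hen counts per week of lay in the reference population (week 1..24).
WEEKLY_HEN_COUNT = np.array(
    [7422, 7351, 7332, 7310, 7296, 7284, 7259, 7231, 7205, 7184, 7132, 7055,
     7022, 6972, 6937, 6883, 6823, 6683, 6592, 6427, 6081, 5719, 5101, 3478]
)

#: Mean weekly egg number in the reference population (week 1..24).
WEEKLY_EGG_MEAN = np.array(
    [5.21, 5.26, 5.30, 5.22, 5.16, 5.06, 4.94, 4.85, 4.77, 4.71, 4.58, 4.50,
     4.38, 4.29, 4.16, 4.09, 3.98, 3.91, 3.88, 3.84, 3.82, 3.82, 3.73, 3.53]
)

#: SD of weekly egg number in the reference population (week 1..24).
WEEKLY_EGG_SD = np.array(
    [1.34, 1.47, 1.48, 1.49, 1.51, 1.53, 1.53, 1.54, 1.52, 1.51, 1.50, 1.49,
     1.47, 1.47, 1.45, 1.44, 1.44, 1.43, 1.41, 1.40, 1.37, 1.35, 1.30, 1.30]
)

#: Age-at-first-egg classes (weeks of age): 29-31, 32-34, >34.
AFE_CLASSES = ("29-31", "32-34", ">34")

#: Default VanRaden-G blending weight: G_blend = w*G + (1-w)*A22.
DEFAULT_BLEND_WEIGHT = 0.95

#: Genotype QC defaults: minimum minor allele frequency, minimum call rate.
DEFAULT_MAF_MIN = 0.05
DEFAULT_CALLRATE_MIN = 0.95

#: Forward-validation fraction (youngest hens whose records are masked).
DEFAULT_VALIDATION_FRACTION = 0.10

#: Persistency defaults: slope from the peak week to a later reference week.
PERSISTENCY_PEAK_WEEK = 3
PERSISTENCY_END_WEEK = 18
PERSISTENCY_DIVISOR = 16.0
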