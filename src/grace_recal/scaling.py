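"""Fixed reference constants for standardising continuous GRACE covariates.

Both the synthetic-cohort generator and the logistic design builder centre and
scale continuous covariates with these constants, so fitted coefficients are
on a per-reference-SD scale and are directly comparable with (and recoverable
against) the generator's own coefficients.  The locations/scales approximate
the covariate marginals of a UK acute-coronary-syndrome registry population
(age in years, heart rate in beats/min, systolic blood pressure in mm Hg,
creatinine in umol/L).
"""

#: column -> (reference location, reference scale)
STANDARDISATION: dict[str, tuple[float, float]] = {
    "age": (67.0, 14.0),
    "heart_rate": (81.0, 22.0),
    "systolic_bp": (139.7, 28.7),
    "creatinine": (101.0, 57.0),
}


def standardise(values, column: str):
    """Return ``(values - location) / scale`` for a continuous GRACE covariate."""
    loc, scale = STANDARDISATION[column]
    return (values - loc) / scale
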