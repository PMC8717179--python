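"""Reference coefficient estimates from the published florbetaben mouse study.

The printed regression table of the florbetaben study in APPPS1 and
App^NL-G-F mice reports, for the two most complete nested models
(fibrillar x nonfibrillar x heterogeneity, and the same plus age), the
fibrillar and nonfibrillar coefficients with their bootstrap 95% CIs.
These numbers serve as worked-example inputs for
:func:`petdecomp.regression.summarize_coefficients`: averaging them yields
the headline values of 3.17 z / % fibrillar area, 0.20 z / % nonfibrillar
area, a 16-fold ratio, and an opposite-CI-edge range of 11- to 26-fold.
"""

#: Coefficients (z units per % area) of the two most complete published models.
PUBLISHED_COEFFICIENTS = (
    {"fibrillar": 3.521, "nonfibrillar": 0.259},
    {"fibrillar": 2.810, "nonfibrillar": 0.146},
)

#: Matching bootstrap 95% CIs (1000 resamples in the source analysis).
PUBLISHED_CIS = (
    {"fibrillar": (2.954, 4.041), "nonfibrillar": (0.178, 0.341)},
    {"fibrillar": (2.620, 3.032), "nonfibrillar": (0.103, 0.193)},
)


def published_summary():
    """The coefficient summary implied by the published table."""
    from .regression import summarize_coefficients

    return summarize_coefficients(PUBLISHED_COEFFICIENTS, PUBLISHED_CIS)
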