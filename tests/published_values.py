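"""Frozen published values of the KWZ extraction-optimization study.

Coefficient vectors follow the package's model-matrix order: intercept,
linear (ethanol, temperature, ratio, time), pairwise interactions in
lexicographic order, pure quadratics.  ANOVA entries are (SS, F) with F
None where the source prints none.
"""

# Coded-unit model equations as published (some terms of the aglu and
# abts equations are typos against the published run table; see the
# acceptance tests).
COEFFICIENTS = {
    "yield": [38.94, -0.77, 1.48, 3.75, -0.23,
              0.19, -0.97, 1.28, 0.36, -1.38, 0.063,
              -2.81, -1.62, -3.12, -0.73],
    "tpc": [47.69, 0.27, -0.42, 2.13, -1.22,
            0.62, -2.51, 0.13, -2.90, -0.090, -3.38,
            -0.75, 0.43, -5.83, -1.73],
    "ptp1b": [86.12, -1.73, 2.89, -2.24, 2.37,
              -0.13, 1.94, -2.66, -1.44, 4.37, -5.86,
              -3.95, -2.36, -2.66, -10.86],
    "aglu": [96.63, 1.04, -2.99, -0.79, 2.06,
             10.73, 1.50, -6.73, 0.42, -1.70, 4.42,
             -0.98, -7.58, -1.73, -4.66],
    "abts": [75.91, 2.73, 3.70, 4.64, -1.43,
             8.08, 5.21, 4.05, 1.48, 3.08, 6.83,
             -2.12, -11.41, -6.20, -7.65],
}

# Published ANOVA panels: {row: (SS, F)} plus R^2 / adjusted R^2.
ANOVA = {
    "yield": {
        "model": (321.42, 10.37), "residual": (31.00, None),
        "pure_error": (1.17, None), "lack_of_fit": (29.83, 10.24),
        "total": (352.41, None), "r2": 0.9120, "adj_r2": 0.8241,
    },
    "tpc": {
        "model": (423.50, 47.38), "residual": (8.94, None),
        "pure_error": (2.49, None), "lack_of_fit": (6.45, 1.04),
        "total": (432.42, None), "r2": 0.9793, "adj_r2": 0.9587,
    },
    "ptp1b": {
        "model": (1318.42, 9.82), "residual": (134.24, None),
        "pure_error": (31.82, None), "lack_of_fit": (102.42, 1.29),
        "total": (1452.66, None), "r2": 0.9076, "adj_r2": 0.8152,
    },
    "aglu": {
        "model": (1449.06, 10.43), "residual": (138.87, None),
        "pure_error": (11.50, None), "lack_of_fit": (127.37, 4.43),
        "total": (1587.93, None), "r2": 0.9125, "adj_r2": 0.8251,
    },
    "abts": {
        "model": (2213.57, 33.37), "residual": (66.33, None),
        "pure_error": (8.87, None), "lack_of_fit": (57.46, 2.59),
        "total": (2279.90, None), "r2": 0.9709, "adj_r2": 0.9418,
    },
}

# Extraction-yield terms reported significant at alpha = 0.05.
YIELD_SIGNIFICANT = {"temperature", "ratio", "ethanol^2", "temperature^2", "ratio^2"}

# Published factor-influence rankings (decreasing linear-effect magnitude).
RANKINGS = {
    "tpc": ["ratio", "time", "temperature", "ethanol"],
    "ptp1b": ["temperature", "time", "ratio", "ethanol"],
    "abts": ["ratio", "temperature", "ethanol", "time"],
}

# Five center-replicate extraction yields (pure-error source).
CENTER_YIELDS = [39.14, 39.27, 38.03, 38.88, 39.37]

# Published total of the 12 component contents (percent w/w).
TOTAL_CONTENT = 11.18
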