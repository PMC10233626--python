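"""Curated hairpin backbone dihedral templates (degrees).

Keyed by (strand_length, loop_length, include_second_hbond). Each template
was solved by restrained least squares against its blueprint hydrogen-bond
pattern (Kabsch-Sander energy targets, steric floors, ladder-extension
avoidance), validated through the motif pipeline at zero noise, and
selected for label-recovery robustness under coordinate noise; see
synthetic.py and docs/methods.md.
"""

TEMPLATES = {
    (4, 4, False): {
        "phi": [-139.0, 83.44, -104.68, -99.04, -72.37, 63.64, 113.04, 174.17, 129.95, 150.42, -149.31, -8.99],
        "psi": [121.27, 4.95, -159.91, -148.98, -143.32, -165.21, -6.01, 54.39, 121.87, 29.94, -120.97, 135.0],
    },
    (4, 5, False): {
        "phi": [-139.0, -32.37, -116.18, 38.47, 5.35, 121.31, -128.5, 147.78, -73.28, 104.45, -70.46, -61.51, 4.31],
        "psi": [120.62, 138.69, -96.36, 54.24, -124.96, 114.79, -102.06, 71.83, -86.93, 18.87, 158.38, 132.42, 135.0],
    },
    (4, 6, False): {
        "phi": [-139.0, 76.73, 102.49, 30.56, 67.31, 171.67, 80.98, -150.52, 165.18, -140.52, 142.24, -75.48, 35.55, -4.65],
        "psi": [-120.13, -171.54, -11.48, 58.31, 12.9, -61.9, 94.1, -78.58, 76.17, 49.49, 20.96, 60.18, -71.92, 135.0],
    },
    (4, 5, True): {
        "phi": [-139.0, 93.47, -113.56, 19.9, -33.48, -9.19, 89.79, 74.63, -73.51, 153.0, -139.54, 95.83, 174.27],
        "psi": [-5.51, -2.23, -149.89, 54.04, 59.06, 157.38, -9.48, 179.86, -51.95, 28.42, -63.77, -50.21, 135.0],
    },
    (4, 6, True): {
        "phi": [-139.0, 39.28, 113.94, -44.22, -1.44, 9.42, -82.71, -72.51, -35.54, 107.15, -105.44, 69.06, 54.39, -19.96],
        "psi": [117.04, -143.4, 96.89, -55.73, -69.27, -168.07, 12.51, 167.27, -47.99, 92.47, -20.68, -153.47, -125.44, 135.0],
    },
}
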