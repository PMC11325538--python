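"""Published BRD4(2) bromodomain ABFE benchmark values, bundled as fixtures.

These are printed per-component free energies (kcal/mol) from a public
benchmark of the split double-decoupling and merged SDR schemes on the
second bromodomain of BRD4 with a fragment ligand: five docked poses plus
the cocrystal structure, long protocols and short-protocol replicas. They
exercise the cycle arithmetic (component sums, merged-vs-split closure,
replica statistics, protocol-time accounting) without any simulation.

Values are (value, uncertainty) tuples; uncertainties for replicas come
from block analysis, for averages from the across-replica spread.
"""

# Merged-scheme components per pose (site→bulk direction): m, e, v, n.
# Split counterparts are the printed sums a+l+t, e+f, v+w, b+c+r.
MERGED_COMPONENTS = {
    "pose 1": {"m": (28.2, 0.6), "e": (-0.7, 0.3), "v": (12.2, 1.0), "n": (-37.3, 0.6)},
    "pose 2": {"m": (26.5, 0.3), "e": (3.2, 0.2), "v": (12.4, 0.6), "n": (-36.1, 0.2)},
    "pose 3": {"m": (28.2, 0.4), "e": (-1.2, 0.3), "v": (12.1, 0.4), "n": (-35.4, 0.3)},
    "pose 4": {"m": (31.2, 0.6), "e": (0.3, 0.3), "v": (7.7, 0.9), "n": (-37.6, 0.5)},
    "pose 5": {"m": (26.3, 0.3), "e": (3.6, 0.1), "v": (12.7, 0.4), "n": (-35.3, 0.6)},
}

SPLIT_SUMS = {
    "pose 1": {"a+l+t": (29.3, 0.4), "e+f": (-0.5, 0.2), "v+w": (12.5, 0.6), "b+c+r": (-38.4, 0.5)},
    "pose 2": {"a+l+t": (26.5, 0.3), "e+f": (3.5, 0.3), "v+w": (12.1, 0.6), "b+c+r": (-36.2, 0.5)},
    "pose 3": {"a+l+t": (27.8, 0.4), "e+f": (-1.4, 0.3), "v+w": (11.5, 0.9), "b+c+r": (-36.5, 0.4)},
    "pose 4": {"a+l+t": (31.6, 0.4), "e+f": (0.5, 0.3), "v+w": (6.6, 0.8), "b+c+r": (-37.4, 0.3)},
    "pose 5": {"a+l+t": (26.5, 0.3), "e+f": (2.8, 0.4), "v+w": (13.5, 0.5), "b+c+r": (-35.9, 0.3)},
}

# Long merged-scheme binding free energies (100.8 ns protocol).
MERGED_LONG_DG = {
    "crystal": (-6.2, 1.1), "pose 1": (-2.4, 1.4), "pose 2": (-6.1, 0.7),
    "pose 3": (-3.7, 0.8), "pose 4": (-1.5, 1.2), "pose 5": (-7.2, 0.8),
}

# Six short-protocol replicas per pose: tevb (17.4 ns) and m*evbc (20.4 ns).
TEVB_REPLICAS = {
    "pose 1": [-2.5, -0.5, -3.1, -1.2, -3.4, -1.2],
    "pose 2": [-6.9, -7.2, -4.5, -8.6, -8.1, -6.0],
    "pose 3": [0.0, -1.0, -4.0, -2.2, -2.1, -3.1],
    "pose 4": [-2.0, -0.2, -1.7, -0.6, -2.7, -3.3],
    "pose 5": [-8.6, -8.7, -8.4, -7.4, -6.9, -6.5],
}

MSTAR_EVBC_REPLICAS = {
    "pose 1": [-3.3, -3.6, -1.8, -3.4, -3.2, -1.8],
    "pose 2": [-7.2, -7.4, -7.4, -7.6, -7.0, -7.4],
    "pose 3": [-2.2, -3.2, -2.7, -3.5, -3.0, -2.6],
    "pose 4": [-1.1, -3.3, 0.5, -1.3, -0.7, -2.4],
    "pose 5": [-8.1, -6.2, -7.2, -8.9, -6.9, -6.8],
}

# Total simulation time per calculation, ns.
PROTOCOL_TOTALS_NS = {
    "first-generation split": 1160.0,
    "split": 148.0,
    "merged": 100.8,
    "tevb": 17.4,
    "m*evbc": 20.4,
}
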