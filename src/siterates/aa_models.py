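"""Empirical amino-acid replacement models (JTT, LG, WAG).

Exchangeabilities are the standard published lower-triangle values in the
canonical ARNDCQEGHILKMFPSTWYV ordering, paired with each model's
equilibrium residue frequencies. :func:`get_replacement_matrix` assembles
the reversible rate matrix ``q_ab = s_ab * pi_b`` scaled to mean rate 1
(one expected replacement per site per unit time at stationarity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genetic_code import AMINO_ACIDS

__all__ = ["ReplacementModel", "get_replacement_matrix", "AVAILABLE_MODELS"]

# lower triangle (row 2 onward) of the symmetric JTT exchangeability matrix
_JTT_S = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9, 11, 298,
    45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101, 64, 126, 20, 17,
    528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15, 503, 232, 8, 70, 16, 10, 49,
    767, 130, 112, 11, 7, 26, 15, 4, 15, 59, 38, 4, 46, 31, 9, 5, 59, 69, 17, 23, 7,
    31, 78, 14, 223, 42, 115, 209, 62, 323, 26, 597, 9, 72, 292, 43, 4, 164, 53, 51,
    18, 24, 20, 119, 26, 12, 9, 181, 18, 5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14,
    5, 24, 201, 33, 55, 8, 47, 16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11, 229, 21,
    479, 89, 10, 40, 245, 9, 32, 961, 14, 388, 248, 102, 59, 25, 52, 24, 180, 65, 4,
    21, 47, 103, 10, 8, 14, 43, 16, 29, 226, 24, 18, 323, 17, 92, 12, 53, 536, 62,
    285, 118, 6, 10, 23, 477, 35, 63, 38, 12, 21, 112, 71, 25, 16
]

_JTT_PI = [
    0.076748, 0.051691, 0.042645, 0.051544, 0.019803, 0.040752, 0.06183, 0.073152,
    0.022944, 0.053761, 0.091904, 0.058676, 0.023826, 0.040126, 0.050901, 0.068765,
    0.058565, 0.014261, 0.032102, 0.066005
]

# lower triangle (row 2 onward) of the symmetric LG exchangeability matrix
_LG_S = [
    0.425093, 0.276818, 0.395144, 2.489084, 0.969894, 1.038545, 2.06604, 0.358858,
    0.14983, 0.395337, 0.536518, 1.124035, 0.253701, 1.177651, 4.727182, 2.139501,
    0.180717, 0.218959, 2.54787, 0.751878, 0.123954, 0.534551, 2.807908, 0.36397,
    0.390192, 2.426601, 0.126991, 0.301848, 6.326067, 0.484133, 0.052722, 0.332533,
    0.858151, 0.578987, 0.593607, 0.31444, 0.170887, 5.076149, 0.528768, 1.695752,
    0.541712, 1.437645, 4.509238, 0.191503, 0.068427, 2.145078, 0.371004, 0.089525,
    0.161787, 4.008358, 2.000679, 0.045376, 0.612025, 0.083688, 0.062556, 0.523386,
    5.24387, 0.844926, 0.927114, 0.01069, 0.015076, 0.282959, 0.025548, 0.017416,
    0.394456, 1.240275, 0.42586, 0.02989, 0.135107, 0.037967, 0.084808, 0.003499,
    0.569265, 0.640543, 0.320627, 0.594007, 0.013266, 0.89368, 1.105251, 0.075382,
    2.784478, 1.14348, 0.670128, 1.165532, 1.959291, 4.128591, 0.267959, 4.813505,
    0.072854, 0.582457, 3.234294, 1.672569, 0.035855, 0.624294, 1.223828, 1.080136,
    0.236199, 0.257336, 0.210332, 0.348847, 0.423881, 0.044265, 0.069673, 1.807177,
    0.173735, 0.018811, 0.419409, 0.611973, 0.604545, 0.077852, 0.120037, 0.245034,
    0.311484, 0.008705, 0.044261, 0.296636, 0.139538, 0.089586, 0.196961, 1.73999,
    0.129836, 0.268491, 0.054679, 0.076701, 0.108882, 0.366317, 0.697264, 0.442472,
    0.682139, 0.508851, 0.990012, 0.584262, 0.597054, 5.306834, 0.119013, 4.145067,
    0.159069, 4.273607, 1.112727, 0.078281, 0.064105, 1.033739, 0.11166, 0.232523,
    10.649107, 0.1375, 6.312358, 2.592692, 0.24906, 0.182287, 0.302936, 0.619632,
    0.299648, 1.702745, 0.656604, 0.023918, 0.390322, 0.748683, 1.136863, 0.049906,
    0.131932, 0.185202, 1.798853, 0.099849, 0.34696, 2.020366, 0.696175, 0.481306,
    1.898718, 0.094464, 0.361819, 0.165001, 2.457121, 7.803902, 0.654683, 1.338132,
    0.571468, 0.095131, 0.089613, 0.296501, 6.472279, 0.248862, 0.400547, 0.098369,
    0.140825, 0.245841, 2.188158, 3.151815, 0.18951, 0.249313
]

_LG_PI = [
    0.079066, 0.055941, 0.041977, 0.053052, 0.012937, 0.040767, 0.071586, 0.057337,
    0.022355, 0.062157, 0.099081, 0.0646, 0.022951, 0.042302, 0.04404, 0.061197,
    0.053287, 0.012066, 0.034155, 0.069147
]

# lower triangle (row 2 onward) of the symmetric WAG exchangeability matrix
_WAG_S = [
    0.551571, 0.509848, 0.738998, 1.02704, 0.908598, 1.58285, 1.41672, 0.316954,
    0.193335, 0.397915, 0.906265, 0.893496, 0.210494, 1.43855, 3.37079, 2.12111,
    0.113133, 0.240735, 2.00601, 0.635346, 0.147304, 0.528191, 3.0355, 0.439157,
    0.584665, 2.13715, 0.186979, 0.497671, 5.35142, 0.683162, 0.102711, 0.679489,
    1.22419, 0.554413, 1.16392, 0.381533, 0.251849, 5.42942, 0.265256, 1.54364,
    0.947198, 1.12556, 3.95629, 0.554236, 0.131528, 3.01201, 0.198221, 0.096162,
    0.195081, 3.97423, 2.03006, 0.071917, 1.086, 0.196246, 0.030295, 0.616783,
    6.17416, 0.865584, 0.930676, 0.039437, 0.084805, 0.479855, 0.103754, 0.04673,
    0.423984, 1.07176, 0.374866, 0.129767, 0.325711, 0.152335, 0.098818, 0.021352,
    0.306674, 0.248972, 0.170135, 0.384287, 0.074034, 0.390482, 0.39802, 0.109404,
    1.40766, 0.512984, 0.71707, 0.543833, 1.00214, 5.46947, 0.330052, 4.29411,
    0.113917, 0.869489, 3.8949, 1.54526, 0.099921, 0.933372, 1.02887, 0.857928,
    0.215737, 0.22771, 0.301281, 0.567717, 0.570025, 0.127395, 0.154263, 2.58443,
    0.315124, 0.081134, 0.682355, 0.704939, 0.822765, 0.156557, 0.196303, 0.588731,
    0.24941, 0.03045, 0.061304, 0.373558, 0.1741, 0.049931, 0.24357, 1.34182,
    0.225833, 0.336983, 0.103604, 0.187247, 0.13819, 0.499462, 0.890432, 0.404141,
    0.679371, 0.696198, 0.740169, 0.473307, 0.262569, 3.87344, 0.118358, 3.17097,
    0.323832, 4.25746, 1.05947, 0.099929, 0.31944, 1.45816, 0.212483, 0.42017,
    7.8213, 0.257555, 4.85402, 2.11517, 0.415844, 0.344739, 0.326622, 0.665309,
    0.398618, 1.80034, 0.934276, 0.088836, 0.556896, 0.96713, 1.38698, 0.137505,
    0.133264, 0.305434, 1.19063, 0.171329, 0.493905, 1.51612, 0.515706, 0.428437,
    2.05845, 0.161444, 0.545931, 0.171903, 1.52964, 6.45428, 0.649892, 1.61328,
    0.795384, 0.139405, 0.216046, 0.314887, 4.37802, 0.523742, 0.786993, 0.232739,
    0.110864, 0.291148, 1.38823, 2.48539, 0.365369, 0.31473
]

_WAG_PI = [
    0.086628, 0.043972, 0.039089, 0.057045, 0.019308, 0.036728, 0.058059, 0.083252,
    0.024431, 0.048466, 0.086209, 0.062029, 0.019503, 0.038432, 0.045763, 0.069518,
    0.061013, 0.014386, 0.035274, 0.070896
]

@dataclass(frozen=True)
class ReplacementModel:
    """A reversible 20-state replacement process for relative-rate inference."""

    name: str
    exchangeabilities: np.ndarray  # (20, 20) symmetric, zero diagonal
    frequencies: np.ndarray  # (20,) equilibrium residue frequencies

    @property
    def rate_matrix(self) -> np.ndarray:
        """``q_ab = s_ab * pi_b``, diagonal for zero row sums, mean rate 1."""
        pi = self.frequencies
        q = self.exchangeabilities * pi[None, :]
        np.fill_diagonal(q, 0.0)
        q /= pi @ q.sum(axis=1)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q


def _assemble(name: str, tri: list, pi: list) -> ReplacementModel:
    s = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            s[i, j] = s[j, i] = tri[k]
            k += 1
    assert k == 190
    p = np.asarray(pi, dtype=float)
    p = p / p.sum()
    return ReplacementModel(name=name, exchangeabilities=s, frequencies=p)


_MODELS = {
    "JTT": _assemble("JTT", _JTT_S, _JTT_PI),
    "LG": _assemble("LG", _LG_S, _LG_PI),
    "WAG": _assemble("WAG", _WAG_S, _WAG_PI),
}

AVAILABLE_MODELS = tuple(_MODELS)


def get_replacement_matrix(name: str = "JTT") -> ReplacementModel:
    """Look up an empirical replacement model by name (JTT, LG, or WAG)."""
    try:
        return _MODELS[name.upper()]
    except KeyError:
        raise ValueError(
            f"unknown replacement model {name!r}; available: {', '.join(_MODELS)}"
        ) from None


assert len(AMINO_ACIDS) == 20
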