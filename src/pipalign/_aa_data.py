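"""Published amino-acid replacement model constants.

WAG (Whelan & Goldman 2001) and LG (Le & Gascuel 2008) empirical
exchangeabilities (lower triangle, row-wise, PAML order ARNDCQEGHILKMFPSTWYV)
with their published stationary frequencies.
"""

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

WAG_EXCH = [
    0.551571, 0.509848, 0.738998, 1.02704, 0.908598,
    1.58285, 1.41672, 0.316954, 0.193335, 0.397915,
    0.906265, 0.893496, 0.210494, 1.43855, 3.37079,
    2.12111, 0.113133, 0.240735, 2.00601, 0.635346,
    0.147304, 0.528191, 3.0355, 0.439157, 0.584665,
    2.13715, 0.186979, 0.497671, 5.35142, 0.683162,
    0.102711, 0.679489, 1.22419, 0.554413, 1.16392,
    0.381533, 0.251849, 5.42942, 0.265256, 1.54364,
    0.947198, 1.12556, 3.95629, 0.554236, 0.131528,
    3.01201, 0.198221, 0.0961621, 0.195081, 3.97423,
    2.03006, 0.0719167, 1.086, 0.196246, 0.0302949,
    0.616783, 6.17416, 0.865584, 0.930676, 0.039437,
    0.0848047, 0.479855, 0.103754, 0.0467304, 0.423984,
    1.07176, 0.374866, 0.129767, 0.325711, 0.152335,
    0.0988179, 0.021352, 0.306674, 0.248972, 0.170135,
    0.384287, 0.0740339, 0.390482, 0.39802, 0.109404,
    1.40766, 0.512984, 0.71707, 0.543833, 1.00214,
    5.46947, 0.330052, 4.29411, 0.113917, 0.869489,
    3.8949, 1.54526, 0.0999208, 0.933372, 1.02887,
    0.857928, 0.215737, 0.22771, 0.301281, 0.567717,
    0.570025, 0.127395, 0.154263, 2.58443, 0.315124,
    0.0811339, 0.682355, 0.704939, 0.822765, 0.156557,
    0.196303, 0.588731, 0.24941, 0.0304501, 0.0613037,
    0.373558, 0.1741, 0.049931, 0.24357, 1.34182,
    0.225833, 0.336983, 0.103604, 0.187247, 0.13819,
    0.499462, 0.890432, 0.404141, 0.679371, 0.696198,
    0.740169, 0.473307, 0.262569, 3.87344, 0.118358,
    3.17097, 0.323832, 4.25746, 1.05947, 0.0999288,
    0.31944, 1.45816, 0.212483, 0.42017, 7.8213,
    0.257555, 4.85402, 2.11517, 0.415844, 0.344739,
    0.326622, 0.665309, 0.398618, 1.80034, 0.934276,
    0.088836, 0.556896, 0.96713, 1.38698, 0.137505,
    0.133264, 0.305434, 1.19063, 0.171329, 0.493905,
    1.51612, 0.515706, 0.428437, 2.05845, 0.161444,
    0.545931, 0.171903, 1.52964, 6.45428, 0.649892,
    1.61328, 0.795384, 0.139405, 0.216046, 0.314887,
    4.37802, 0.523742, 0.786993, 0.232739, 0.110864,
    0.291148, 1.38823, 2.48539, 0.365369, 0.31473,
]

WAG_FREQS = [
    0.08662790866279087, 0.04397200439720044, 0.0390894039089404, 0.057045105704510574, 0.019307801930780195,
    0.03672810367281037, 0.05805890580589058, 0.08325180832518084, 0.024431302443130246, 0.04846600484660049,
    0.08620900862090086, 0.062028606202860624, 0.019502701950270197, 0.03843190384319038, 0.045763104576310464,
    0.06951790695179069, 0.06101270610127062, 0.014385901438590145, 0.035274203527420354, 0.07089560708956072,
]

LG_EXCH = [
    0.425093, 0.276818, 0.395144, 2.489084, 0.969894,
    1.038545, 2.06604, 0.358858, 0.14983, 0.395337,
    0.536518, 1.124035, 0.253701, 1.177651, 4.727182,
    2.139501, 0.180717, 0.218959, 2.54787, 0.751878,
    0.123954, 0.534551, 2.807908, 0.36397, 0.390192,
    2.426601, 0.126991, 0.301848, 6.326067, 0.484133,
    0.052722, 0.332533, 0.858151, 0.578987, 0.593607,
    0.31444, 0.170887, 5.076149, 0.528768, 1.695752,
    0.541712, 1.437645, 4.509238, 0.191503, 0.068427,
    2.145078, 0.371004, 0.089525, 0.161787, 4.008358,
    2.000679, 0.045376, 0.612025, 0.083688, 0.062556,
    0.523386, 5.24387, 0.844926, 0.927114, 0.01069,
    0.015076, 0.282959, 0.025548, 0.017416, 0.394456,
    1.240275, 0.42586, 0.02989, 0.135107, 0.037967,
    0.084808, 0.003499, 0.569265, 0.640543, 0.320627,
    0.594007, 0.013266, 0.89368, 1.105251, 0.075382,
    2.784478, 1.14348, 0.670128, 1.165532, 1.959291,
    4.128591, 0.267959, 4.813505, 0.072854, 0.582457,
    3.234294, 1.672569, 0.035855, 0.624294, 1.223828,
    1.080136, 0.236199, 0.257336, 0.210332, 0.348847,
    0.423881, 0.044265, 0.069673, 1.807177, 0.173735,
    0.018811, 0.419409, 0.611973, 0.604545, 0.077852,
    0.120037, 0.245034, 0.311484, 0.008705, 0.044261,
    0.296636, 0.139538, 0.089586, 0.196961, 1.73999,
    0.129836, 0.268491, 0.054679, 0.076701, 0.108882,
    0.366317, 0.697264, 0.442472, 0.682139, 0.508851,
    0.990012, 0.584262, 0.597054, 5.306834, 0.119013,
    4.145067, 0.159069, 4.273607, 1.112727, 0.078281,
    0.064105, 1.033739, 0.11166, 0.232523, 10.649107,
    0.1375, 6.312358, 2.592692, 0.24906, 0.182287,
    0.302936, 0.619632, 0.299648, 1.702745, 0.656604,
    0.023918, 0.390322, 0.748683, 1.136863, 0.049906,
    0.131932, 0.185202, 1.798853, 0.099849, 0.34696,
    2.020366, 0.696175, 0.481306, 1.898718, 0.094464,
    0.361819, 0.165001, 2.457121, 7.803902, 0.654683,
    1.338132, 0.571468, 0.095131, 0.089613, 0.296501,
    6.472279, 0.248862, 0.400547, 0.098369, 0.140825,
    0.245841, 2.188158, 3.151815, 0.18951, 0.249313,
]

LG_FREQS = [
    0.07906592093407908, 0.05594094405905594, 0.04197695802304198, 0.053051946948053055, 0.012936987063012939,
    0.040766959233040766, 0.07158592841407159, 0.05733694266305734, 0.022354977645022357, 0.06215693784306216,
    0.09908090091909909, 0.0645999354000646, 0.022950977049022953, 0.042301957698042306, 0.04403995596004404,
    0.0611969388030612, 0.05328694671305329, 0.012065987934012068, 0.034154965845034156, 0.06914693085306915,
]
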