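"""Published per-period "high in" counts for the Chilean packaged-food supply.

The underlying label database is not public, but the published repeated
cross-sectional analysis prints, for each stratum and flag, the number
of products classified "high in" and the stratum size in each period
(T0 = pooled 2015/2016 baseline, then 2017, 2019, 2020).  Those (k, n)
pairs are sufficient inputs for the whole proportion machinery —
prevalence percents, percentage-point differences, Firth EMM contrasts
and trend tests — so they are shipped here as reference data.

Keys are ``(stratum, flag)``; values are four ``(k, n)`` pairs in period
order.
"""

PERIOD_ORDER = ("T0", "T1", "T2", "T3")

#: Whole-supply strata (all products / solids only / liquids only).
STRATA_COUNTS = {
    ("overall", "any"): ((2735, 3864), (1536, 2424), (1671, 3065), (1517, 2888)),
    ("overall", "energy"): ((1365, 3864), (922, 2424), (976, 3065), (931, 2888)),
    ("overall", "sugars"): ((1313, 3864), (804, 2424), (780, 3065), (679, 2888)),
    ("overall", "satfat"): ((1071, 3864), (658, 2424), (721, 3065), (664, 2888)),
    ("overall", "sodium"): ((1300, 3864), (644, 2424), (800, 3065), (665, 2888)),
    ("solids", "any"): ((2051, 2547), (1290, 1694), (1434, 2036), (1253, 1875)),
    ("solids", "energy"): ((1175, 2547), (875, 1694), (921, 2036), (873, 1875)),
    ("solids", "sugars"): ((873, 2547), (668, 1694), (660, 2036), (560, 1875)),
    ("solids", "satfat"): ((971, 2547), (625, 1694), (682, 2036), (621, 1875)),
    ("solids", "sodium"): ((1066, 2547), (542, 1694), (697, 2036), (537, 1875)),
    ("liquids", "any"): ((684, 1317), (246, 730), (237, 1029), (264, 1013)),
    ("liquids", "energy"): ((190, 1317), (47, 730), (55, 1029), (58, 1013)),
    ("liquids", "sugars"): ((440, 1317), (136, 730), (120, 1029), (119, 1013)),
    ("liquids", "satfat"): ((100, 1317), (33, 730), (39, 1029), (43, 1013)),
    ("liquids", "sodium"): ((234, 1317), (102, 730), (103, 1029), (128, 1013)),
}

#: A few group-level rows with large published reformulation effects.
GROUP_COUNTS = {
    ("breakfast_cereals", "sugars"): ((143, 171), (79, 102), (81, 128), (48, 111)),
    ("sweet_spreads", "sugars"): ((69, 119), (15, 57), (20, 88), (10, 73)),
    ("savory_baked", "sodium"): ((78, 148), (66, 121), (25, 109), (14, 114)),
    ("meat_products", "sodium"): ((188, 356), (47, 93), (47, 202), (25, 180)),
}
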