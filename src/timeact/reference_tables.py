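"""Published evaluation contingency tables for the two classifiers.

These 4x4 count matrices are the printed evaluation results of the original
HCTLS / UCI study that this package's classifiers re-implement: the
rule-based model evaluated against both datasets, and the two random-forest
models under 10-fold cross-validation and cross-dataset transfer.  They are
worked-example inputs for the metrics layer — the counts are data, every
percentage is recomputed here.

Class order everywhere: indoor, outdoor static, outdoor walking, in-vehicle
travel.  The rule-model HCTLS panel was printed in the transposed
orientation (its printed "sensitivity" column is arithmetically a
column-based ratio); its ``transposed_source`` flag records that, and
:meth:`ConfusionMatrix.oriented` normalizes it.
"""
from __future__ import annotations

import numpy as np

from .evaluate import ConfusionMatrix

__all__ = ["RULE_HCTLS", "RULE_UCI", "RF_HCTLS_CV", "RF_HCTLS_ON_UCI",
           "RF_UCI_CV", "RF_UCI_ON_HCTLS", "ALL_TABLES"]

# Rule-based model vs the HCTLS data.  Printed rows labeled "coded", but the
# printed metric triples are only consistent with a transposed layout.
RULE_HCTLS = ConfusionMatrix(np.array([
    [284830,  9840,  1002,  1362],
    [ 51991, 12901,  2336,  5994],
    [  1102,  1145,  9096,   827],
    [   778,  1073,   857, 21127],
]), transposed_source=True)

# Rule-based model vs the supplemental UCI data (standard orientation).
RULE_UCI = ConfusionMatrix(np.array([
    [103930,  5430,   134,   144],
    [  1558,  2298,   169,   214],
    [   284,   764,   646,   193],
    [   114,   336,   176,  4512],
]))

# HCTLS random-forest model, 10-fold cross-validation.
RF_HCTLS_CV = ConfusionMatrix(np.array([
    [21959,  6177,  1604,   260],
    [ 9777,  9749,  3596,  1830],
    [ 1052,  1820,  9931,   477],
    [ 1475,  5307,   750, 21762],
]))

# HCTLS random-forest model applied to the full UCI dataset.
RF_HCTLS_ON_UCI = ConfusionMatrix(np.array([
    [82874, 26278,   170,   314],
    [  850,  3137,    35,   214],
    [  101,   993,   555,   244],
    [    0,   515,    60,  4562],
]))

# UCI random-forest model, 10-fold cross-validation.
RF_UCI_CV = ConfusionMatrix(np.array([
    [3978,   860,   120,    42],
    [ 109,  3285,   471,   371],
    [   0,   170,  1313,   410],
    [   0,   146,   210,  4781],
]))

# UCI random-forest model applied to the full HCTLS dataset.
RF_UCI_ON_HCTLS = ConfusionMatrix(np.array([
    [153216, 54796, 128829,  1894],
    [  3519,  6590,  13015,  1828],
    [   320,   725,  11840,   395],
    [   999,  3464,   3550, 21281],
]))

ALL_TABLES = {
    "rule_hctls": RULE_HCTLS,
    "rule_uci": RULE_UCI,
    "rf_hctls_cv": RF_HCTLS_CV,
    "rf_hctls_on_uci": RF_HCTLS_ON_UCI,
    "rf_uci_cv": RF_UCI_CV,
    "rf_uci_on_hctls": RF_UCI_ON_HCTLS,
}
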