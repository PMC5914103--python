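"""Published benchmark results used as frozen reference inputs.

Mean scores of six imbalanced-learning methods (ensemble of rotation
trees, undersampled rotation forest, EasyEnsemble, BalanceCascade,
Bagging, and a single C4.5 tree) over 10x10 cross-validation on eight
two-class medical benchmark datasets, together with the column averages
the source tables print.  These numbers serve purely as inputs for
table-arithmetic and ranking tests; the package never tries to reproduce
the underlying datasets.
"""

import pandas as pd

METHODS = ["ert", "rurf", "easyensemble", "balancecascade", "bagging", "c45"]
DATASETS = ["d1", "d2", "d3", "d4", "d5", "d6", "d7", "d8"]


def _table(rows):
    return pd.DataFrame(rows, index=DATASETS, columns=METHODS).astype(float)


RECALL = _table(
    [
        [0.5917, 0.2975, 0.4476, 0.4522, 0.2433, 0.2471],
        [0.9946, 0.9847, 0.9643, 0.9660, 0.9502, 0.9198],
        [0.7834, 0.5528, 0.7828, 0.7824, 0.6110, 0.5915],
        [0.8150, 0.4792, 0.7742, 0.7658, 0.3642, 0.3442],
        [0.5300, 0.2300, 0.3000, 0.3000, 0.2900, 0.2800],
        [0.9975, 0.9242, 0.9350, 0.9342, 0.8692, 0.8983],
        [0.9975, 0.9158, 0.9467, 0.9433, 0.8750, 0.8775],
        [0.9861, 0.8884, 0.9805, 0.9814, 0.8658, 0.8684],
    ]
)

F_MEASURE = _table(
    [
        [0.5031, 0.3893, 0.4407, 0.4453, 0.3383, 0.3415],
        [0.9587, 0.9607, 0.9328, 0.9350, 0.9429, 0.9171],
        [0.6884, 0.6196, 0.6749, 0.6749, 0.6434, 0.6148],
        [0.6227, 0.5117, 0.5673, 0.5632, 0.4154, 0.3856],
        [0.3497, 0.2300, 0.1019, 0.1043, 0.2900, 0.2800],
        [0.9483, 0.9408, 0.8831, 0.8881, 0.8987, 0.8974],
        [0.9506, 0.9410, 0.8623, 0.8572, 0.8912, 0.8762],
        [0.8046, 0.9168, 0.7682, 0.7674, 0.8991, 0.8878],
    ]
)

G_MEAN = _table(
    [
        [0.6289, 0.4993, 0.5726, 0.5767, 0.4470, 0.4507],
        [0.9756, 0.9747, 0.9544, 0.9560, 0.9576, 0.9366],
        [0.7573, 0.6945, 0.7443, 0.7444, 0.7173, 0.6947],
        [0.7848, 0.6122, 0.7451, 0.7391, 0.4999, 0.4759],
        [0.5036, 0.2300, 0.2440, 0.2445, 0.2900, 0.2800],
        [0.9873, 0.9553, 0.9449, 0.9457, 0.9224, 0.9334],
        [0.9879, 0.9520, 0.9431, 0.9408, 0.9226, 0.9203],
        [0.9775, 0.9404, 0.9710, 0.9713, 0.9279, 0.9284],
    ]
)

AUC = _table(
    [
        [0.6404, 0.6117, 0.6078, 0.6099, 0.5929, 0.5944],
        [0.9759, 0.9750, 0.9548, 0.9564, 0.9580, 0.9372],
        [0.7592, 0.7157, 0.7472, 0.7473, 0.7295, 0.7099],
        [0.8039, 0.6992, 0.7590, 0.7559, 0.6502, 0.6376],
        [0.7258, 0.6150, 0.5429, 0.5445, 0.6446, 0.6396],
        [0.9876, 0.9590, 0.9478, 0.9488, 0.9299, 0.9403],
        [0.9882, 0.9560, 0.9464, 0.9442, 0.9311, 0.9285],
        [0.9776, 0.9426, 0.9712, 0.9715, 0.9310, 0.9314],
    ]
)

# Column averages as printed in the source tables.
PRINTED_AVERAGES = {
    "recall": [0.8370, 0.6591, 0.7664, 0.7657, 0.6336, 0.6283],
    "f_measure": [0.7283, 0.6887, 0.6539, 0.6544, 0.6649, 0.6501],
    "g_mean": [0.8254, 0.7323, 0.7649, 0.7648, 0.7106, 0.7025],
    "auc": [0.8573, 0.8093, 0.8096, 0.8098, 0.7959, 0.7899],
}

TABLES = {"recall": RECALL, "f_measure": F_MEASURE, "g_mean": G_MEAN, "auc": AUC}
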