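"""Published reference values accompanying the open NSR dataset.

These constants are the results reported with the open NSR dataset release
(figshare DOI 10.6084/m9.figshare.23614809): the per-manual-score ``A_norm``
distribution statistics that calibrate the objective 3-scale, and the pooled
out-of-fold confusion matrices of the SVM screening runs for both feature
schemes.  They serve as regression anchors: metric computations in this
package must reproduce the reported summary metrics from these matrices
exactly, and threshold derivation must reproduce the published cut-points.

All matrices are 2x2 integer arrays with rows = actual (HC, patient) and
columns = predicted (HC, patient); every cohort has 60 healthy controls and
20 patients.
"""

from __future__ import annotations

import numpy as np

from .quantify import ScoreDistributionStats

#: Mean, variance and SD of ``A_norm`` within each manual 4-point score
#: stratum, as published.  The SDs are reported values, not recomputed from
#: the variances (they differ in the third decimal, an artefact of the
#: original estimator), so they are stored verbatim.
SCORE_DISTRIBUTION_STATS = ScoreDistributionStats(
    means=(0.0648, 0.1535, 0.1661, 0.1665),
    variances=(0.0229, 0.0363, 0.0217, 0.0291),
    sds=(0.1515, 0.1907, 0.1477, 0.1706),
)

#: Published cut-points of the objective 3-scale.  The lower one is the
#: stratum-mean midpoint 0.10915 truncated to four decimals.
PUBLISHED_THRESHOLDS = (0.1091, 0.1598)

#: Pooled confusion matrices, 3-scale score features.
CONFUSION_3SCALE: dict[str, np.ndarray] = {
    "BP": np.array([[45, 15], [8, 12]]),
    "SZ": np.array([[47, 13], [7, 13]]),
    "DP": np.array([[53, 7], [8, 12]]),
}

#: Pooled confusion matrices, direct normalised-area features.
CONFUSION_DIRECT: dict[str, np.ndarray] = {
    "BP": np.array([[41, 19], [7, 13]]),
    "SZ": np.array([[36, 24], [6, 14]]),
    "DP": np.array([[33, 27], [5, 15]]),
}

#: Winning SVM/SMOTE hyperparameters reported per comparison and scheme.
BEST_PARAMS: dict[str, dict[str, dict]] = {
    "three_scale": {
        "BP": {"smote_k_neighbors": 7, "C": 0.1, "gamma": 0.01, "kernel": "rbf"},
        "SZ": {"smote_k_neighbors": 5, "C": 10, "degree": 4, "kernel": "poly"},
        "DP": {"smote_k_neighbors": 7, "C": 1, "degree": 2, "kernel": "poly"},
    },
    "direct_area": {
        "BP": {"smote_k_neighbors": 3, "C": 1, "gamma": 1, "kernel": "rbf"},
        "SZ": {"smote_k_neighbors": 3, "C": 1, "degree": 3, "kernel": "poly"},
        "DP": {"smote_k_neighbors": 3, "C": 1, "gamma": 1, "kernel": "rbf"},
    },
}
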