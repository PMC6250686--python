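"""Small bundled reference datasets.

The reference morphometry table holds the published per-sample mean leaf
length, width and leaf index for the 12 *P. euphratica* bud samples (three
biological replicates of each of the four shape classes) that anchor the
stage design used throughout this package.  Note that the printed mean leaf
index is the mean of per-leaf length/width ratios, so it generally differs
from ``mean_length_cm / mean_width_cm`` (e.g. sample Li2: 7.45 vs
3.56/0.50 = 7.12).
"""

from __future__ import annotations

import pandas as pd

_REFERENCE_ROWS = [
    # sample, stage, mean L (cm), mean W (cm), mean LI
    ("Li1", "Li", 2.37, 0.36, 6.78),
    ("Li2", "Li", 3.56, 0.50, 7.45),
    ("Li3", "Li", 2.52, 0.37, 7.10),
    ("La1", "La", 1.96, 0.86, 2.68),
    ("La2", "La", 2.55, 0.75, 4.05),
    ("La3", "La", 2.65, 0.82, 3.39),
    ("Ov1", "Ov", 2.19, 1.36, 1.78),
    ("Ov2", "Ov", 2.17, 1.51, 1.58),
    ("Ov3", "Ov", 2.66, 1.28, 2.07),
    ("Bo1", "Bo", 1.19, 1.63, 0.74),
    ("Bo2", "Bo", 1.31, 1.84, 0.73),
    ("Bo3", "Bo", 1.30, 1.80, 0.74),
]


def reference_morphometry() -> pd.DataFrame:
    """Published mean morphometry of the 12 reference bud samples.

    Returns a DataFrame indexed by ``sample_id`` with columns ``stage``,
    ``mean_length_cm``, ``mean_width_cm`` and ``mean_li``.
    """
    df = pd.DataFrame(
        _REFERENCE_ROWS,
        columns=["sample_id", "stage", "mean_length_cm", "mean_width_cm", "mean_li"],
    )
    return df.set_index("sample_id")
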