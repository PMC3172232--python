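"""Published per-subject performance values of the reference study.

The cross-subject thermal-pain decoding study this package emulates
reported per-subject accuracy, PPV and NPV for a whole-brain linear SVM
tested on an independent 8-subject group (initial validation) and again on
an 8-subject retest group.  Those printed per-subject percentages are
embedded here as inputs, so the package's evaluation arithmetic (group
means, SDs and t-tests against chance) can be checked against the reported
group-level numbers.
"""

from __future__ import annotations

import pandas as pd

_TEST_ROWS = [
    # subject, accuracy %, PPV %, NPV %
    ("1", 75.0, 100.0, 66.7),
    ("2", 85.7, 91.7, 81.2),
    ("3", 82.1, 80.0, 84.6),
    ("4", 100.0, 100.0, 100.0),
    ("5", 71.4, 71.4, 71.4),
    ("6", 96.4, 93.3, 100.0),
    ("7", 85.7, 85.7, 85.7),
    ("8", 96.4, 100.0, 93.3),
]

_RETEST_ROWS = [
    ("1", 64.3, 66.7, 62.5),
    ("2", 85.7, 77.8, 100.0),
    ("3", 64.3, 70.0, 61.1),
    ("4", 71.4, 100.0, 63.6),
    ("5", 67.9, 66.7, 69.2),
    ("6", 92.9, 87.5, 100.0),
    ("7", 60.7, 100.0, 56.0),
    ("8", 89.3, 100.0, 82.4),
]


def published_performance(group: str) -> pd.DataFrame:
    """Published per-subject decoder performance for ``group``.

    ``group`` is ``"test"`` (initial 8-subject validation group) or
    ``"retest"`` (the independent 8-subject retest group).
    """
    rows = {"test": _TEST_ROWS, "retest": _RETEST_ROWS}[group]
    return pd.DataFrame(rows, columns=["subject_id", "accuracy", "ppv", "npv"])
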