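"""Independent brute-force oracles used by several test modules.

The ICC oracle computes the two-way ANOVA decomposition directly from the
definitions of the sums of squares with explicit Python loops — no shared
code with the package implementation — and plugs the mean squares into the
textbook ICC forms.
"""

from __future__ import annotations

import numpy as np


def icc_oracle(table: np.ndarray) -> dict[str, float]:
    """All four two-way ICC forms from first principles."""
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    grand = sum(table[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(table[i][j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_err = sum(
        (table[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    msr = float(ss_rows) / (n - 1)
    msc = float(ss_cols) / (k - 1)
    mse = float(ss_err) / ((n - 1) * (k - 1))
    out = {"msr": msr, "msc": msc, "mse": mse}
    if msr > 0:
        out["consistency_single"] = (msr - mse) / (msr + (k - 1) * mse)
        out["consistency_average"] = (msr - mse) / msr
        out["absolute_single"] = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        out["absolute_average"] = (msr - mse) / (msr + (msc - mse) / n)
    return out


def cronbach_oracle(table: np.ndarray) -> float:
    """Cronbach alpha straight from its defining formula."""
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    item_var = sum(float(np.var(table[:, j], ddof=1)) for j in range(k))
    total_var = float(np.var(table.sum(axis=1), ddof=1))
    return k / (k - 1) * (1.0 - item_var / total_var)
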