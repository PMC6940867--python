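"""Independent brute-force oracles used by the unit and acceptance tests."""

import numpy as np
import pandas as pd
from scipy import stats


def brute_hampel(x, half_window=3, n_sd=3.0, dispersion="mad"):
    """Literal sliding-window Hampel: one window at a time, no vectorisation."""
    x = [float(v) for v in x]
    n = len(x)
    if n < 2 * half_window + 1:
        return list(x), []
    out = list(x)
    flagged = []
    for i in range(n):
        window = x[max(0, i - half_window): min(n, i + half_window + 1)]
        med = float(np.median(window))
        if dispersion == "mad":
            sd = 1.4826 * float(np.median([abs(v - med) for v in window]))
        else:
            sd = float(np.std(window, ddof=1))
        if abs(x[i] - med) > n_sd * sd:
            out[i] = med
            flagged.append(i)
    return out, flagged


def icc_a1_pingouin(criterion, device):
    """ICC(A,1) via pingouin's ANOVA-based implementation."""
    import pingouin as pg

    n = len(criterion)
    df = pd.DataFrame(
        {
            "targets": np.repeat(np.arange(n), 2),
            "raters": np.tile(["criterion", "device"], n),
            "scores": np.column_stack([criterion, device]).ravel(),
        }
    )
    table = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="scores")
    return float(table.loc[table["Type"] == "ICC(A,1)", "ICC"].iloc[0])


def paired_t_power(n, effect, sd_diff, alpha=0.05):
    """Analytic two-sided paired-t power from the noncentral t distribution."""
    ncp = effect / (sd_diff / np.sqrt(n))
    df = n - 1
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
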