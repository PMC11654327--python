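"""Independent oracles used by the test suite.

These deliberately avoid the package's own estimation code paths: the
probability oracle normalises exponentiated cumulative sums directly, and the
likelihood oracle hands a plain negative log-likelihood to a generic scipy
minimiser.
"""

import numpy as np
import pandas as pd
from scipy.optimize import minimize


def probability_oracle(measure, difficulty, severity, thresholds):
    """Category probabilities by direct normalisation of exp-cumulative-sums."""
    theta = measure - difficulty - severity
    unnorm = [1.0]
    for f in thresholds:
        unnorm.append(unnorm[-1] * np.exp(theta - f))
    unnorm = np.array(unnorm)
    return unnorm / unnorm.sum()


def direct_ml_oracle(records: pd.DataFrame):
    """Maximise the joint rating-scale likelihood with a generic optimiser.

    Identification mirrors the JMLE gauge: stations, cohorts and thresholds
    are mean-centred; student measures are free.
    """
    students, s_idx = np.unique(records["student_id"], return_inverse=True)
    stations, i_idx = np.unique(records["station_id"], return_inverse=True)
    cohorts, c_idx = np.unique(records["cohort_id"], return_inverse=True)
    values = np.unique(records["score"])
    k_obs = np.searchsorted(values, records["score"].to_numpy())
    n_s, n_i, n_c, n_k = len(students), len(stations), len(cohorts), len(values)
    kvec = np.arange(n_k)

    def unpack(x):
        b = x[:n_s]
        d = x[n_s : n_s + n_i - 1]
        c = x[n_s + n_i - 1 : n_s + n_i + n_c - 2]
        f = x[n_s + n_i + n_c - 2 :]
        return b, np.append(d, -d.sum()), np.append(c, -c.sum()), np.append(f, -f.sum())

    def nll(x):
        b, D, C, F = unpack(x)
        theta = b[s_idx] - D[i_idx] - C[c_idx]
        s_cum = np.concatenate([[0.0], np.cumsum(F)])
        logits = theta[:, None] * kvec[None, :] - s_cum[None, :]
        m = logits.max(axis=1)
        log_z = np.log(np.exp(logits - m[:, None]).sum(axis=1)) + m
        return -(logits[np.arange(len(k_obs)), k_obs] - log_z).sum()

    x0 = np.zeros(n_s + n_i - 1 + n_c - 1 + n_k - 2)
    res = minimize(
        nll, x0, method="L-BFGS-B",
        options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-10},
    )
    b, D, C, F = unpack(res.x)
    return b, D, C, F, values
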