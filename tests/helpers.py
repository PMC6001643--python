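"""Independent brute-force oracles used by the tests and by nothing else.

These are literal transcriptions of the defining formulas (sums over
subjects, explicit Kaplan-Meier products), deliberately sharing no code with
the package.
"""

import numpy as np


def km_censoring_at_minus(times, d, t):
    """G(t-): literal product of (1 - dc/Y) over censoring times strictly < t."""
    g = 1.0
    for c in sorted(set(times[np.asarray(d) == 0])):
        if c >= t:
            break
        y = float(np.sum(times >= c))
        dc = float(np.sum((times == c) & (np.asarray(d) == 0)))
        g *= 1.0 - dc / y
    return g


def eq_weighted_re_terms(times, d, hazmat, m_weights, tau=np.inf):
    """Per-death (time, numerator, denominator) of the weighted RE ratio.

    ``hazmat`` has one column per death, deaths taken in ascending time
    order (stable within ties); ``m_weights`` is the per-death mode weight
    (1, a cause indicator, or a cancer-death probability).
    """
    times = np.asarray(times, dtype=float)
    d = np.asarray(d, dtype=int)
    death_rows = [i for i in np.argsort(times, kind="stable") if d[i] == 1]
    out = []
    for j, i in enumerate(death_rows):
        tj = times[i]
        if tj > tau:
            continue
        risk = [k for k in range(times.size) if times[k] >= tj]
        li = hazmat[i, j]
        gt = sum(1 for k in risk if hazmat[k, j] > li)
        eq = sum(1 for k in risk if hazmat[k, j] == li)
        r_model = 1.0 + gt + 0.5 * (eq - 1)
        r_null = (len(risk) + 1) / 2.0
        invg = 1.0 / km_censoring_at_minus(times, d, tj)
        m = m_weights[j]
        out.append((tj, invg * m * (r_null - r_model), invg * m * (r_null - 1.0)))
    return out


def eq_weighted_re(times, d, hazmat, m_weights, tau=np.inf):
    terms = eq_weighted_re_terms(times, d, hazmat, m_weights, tau)
    num = sum(a for _, a, _ in terms)
    den = sum(b for _, _, b in terms)
    return num / den if den else np.nan
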