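"""Independent reference implementations used as test oracles.

These deliberately share no code with the package: plain-Python unrolled
recursions and closed forms, kept simple enough to verify by eye.
"""

import math


def oracle_replay(choices, outcomes, a_cp, a_cn, a_up, a_un, tau, v0=(0.0, 0.0)):
    """Hand-unrolled value/RPE/likelihood recursion over a trial sequence.

    ``choices`` are 0/1, ``outcomes`` +1/-1.  Returns per-trial lists of
    (rpe, chosen value, probability of the observed choice) and the summed
    log probability over trials with a predecessor.
    """
    v = [v0[0], v0[1]]
    rpes, v_chosen, p_obs_list = [], [], []
    loglik = 0.0
    n_terms = 0
    prev = None
    for c, r in zip(choices, outcomes):
        x = (v[0] - v[1]) / tau
        if x >= 0:
            p_a = 1.0 / (1.0 + math.exp(-x))
        else:
            p_a = math.exp(x) / (1.0 + math.exp(x))
        p_obs = p_a if c == 0 else 1.0 - p_a
        p_obs_list.append(p_obs)
        if prev is not None:
            loglik += math.log(max(p_obs, 1e-300))
            n_terms += 1
        rpe = r - v[c]
        rpes.append(rpe)
        v_chosen.append(v[c])
        if rpe >= 0:
            v[c] = v[c] + a_cp * rpe
            v[1 - c] = v[1 - c] - a_up * rpe
        else:
            v[c] = v[c] + a_cn * rpe
            v[1 - c] = v[1 - c] - a_un * rpe
        prev = c
    return rpes, v_chosen, p_obs_list, loglik, n_terms


def oracle_mean_loglik(choices, outcomes, a_cp, a_cn, a_up, a_un, tau):
    *_, loglik, n_terms = oracle_replay(choices, outcomes, a_cp, a_cn, a_up, a_un, tau)
    return loglik / n_terms
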