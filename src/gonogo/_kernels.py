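"""JIT-compiled inner loops for likelihood evaluation and agent simulation.

Shared conventions: actions coded 0=go_left, 1=go_right, 2=nogo; valence
coded 1=win, 0=avoid; outcomes in {-1, 0, +1}; Q tables 8 x 3 initialized to
zero.  The learning rate is passed on the unconstrained (logit) scale because
the instrumental-bias construction operates there.  outcome_mode selects how
outcomes are scaled: 0 = single rho, 1 = rho by cue valence, 2 = rho by
context-relative outcome valence (desired -> +rho_a, undesired -> -rho_b).
"""

import numpy as np
from numba import njit

_P_FLOOR = 1e-12
_EPS_CLAMP = 1e-9


@njit(cache=True)
def _effective_rates(eps_hat, kappa, use_kappa):
    eps0 = 1.0 / (1.0 + np.exp(-eps_hat))
    if not use_kappa:
        return eps0, eps0, eps0
    if eps0 <= 0.5:
        eps_pnogo = 1.0 / (1.0 + np.exp(-(eps_hat - kappa)))
        eps_rgo = eps0 + (eps0 - eps_pnogo)
    else:
        eps_rgo = 1.0 / (1.0 + np.exp(-(eps_hat + kappa)))
        eps_pnogo = eps0 + (eps0 - eps_rgo)
    eps_rgo = min(max(eps_rgo, _EPS_CLAMP), 1.0 - _EPS_CLAMP)
    eps_pnogo = min(max(eps_pnogo, _EPS_CLAMP), 1.0 - _EPS_CLAMP)
    return eps0, eps_rgo, eps_pnogo


@njit(cache=True)
def _scaled_outcome(r, v, rho_a, rho_b, outcome_mode):
    if outcome_mode == 0:
        return rho_a * r
    if outcome_mode == 1:
        return (rho_a if v == 1 else rho_b) * r
    desired = (v == 1 and r == 1) or (v == 0 and r == 0)
    return rho_a if desired else -rho_b


@njit(cache=True)
def _pick_rate(r, a, eps0, eps_rgo, eps_pnogo, use_kappa):
    if use_kappa and r == 1 and a != 2:
        return eps_rgo
    if use_kappa and r == -1 and a == 2:
        return eps_pnogo
    return eps0


@njit(cache=True)
def nll_kernel(cue_idx, action, outcome, valence,
               rho_a, rho_b, eps_hat, gobias, pi, kappa,
               outcome_mode, use_kappa):
    """Sequential negative log likelihood of an observed choice sequence."""
    q = np.zeros((8, 3))
    eps0, eps_rgo, eps_pnogo = _effective_rates(eps_hat, kappa, use_kappa)
    total = 0.0
    for t in range(cue_idx.shape[0]):
        c = cue_idx[t]
        a = action[t]
        r = outcome[t]
        v = valence[t]
        pav = pi * (0.5 if v == 1 else -0.5)
        w0 = q[c, 0] + gobias + pav
        w1 = q[c, 1] + gobias + pav
        w2 = q[c, 2]
        m = max(w0, max(w1, w2))
        e0 = np.exp(w0 - m)
        e1 = np.exp(w1 - m)
        e2 = np.exp(w2 - m)
        z = e0 + e1 + e2
        if a == 0:
            p = e0 / z
        elif a == 1:
            p = e1 / z
        else:
            p = e2 / z
        if p < _P_FLOOR:
            p = _P_FLOOR
        total -= np.log(p)
        s = _scaled_outcome(r, v, rho_a, rho_b, outcome_mode)
        lr = _pick_rate(r, a, eps0, eps_rgo, eps_pnogo, use_kappa)
        q[c, a] += lr * (s - q[c, a])
    return total


@njit(cache=True)
def simulate_kernel(cue_idx, valid, req_action, valence_by_cue,
                    rho_a, rho_b, eps_hat, gobias, pi, kappa,
                    outcome_mode, use_kappa, seed):
    """Generate choices and outcomes for one session on a fixed schedule.

    ``req_action`` and ``valence_by_cue`` are per-cue (length-8) lookups.
    Outcomes follow the probabilistic feedback rule: on valid trials the
    correct action earns the favorable outcome of the cue's valence, on
    invalid trials the mapping flips.
    """
    np.random.seed(seed)
    n = cue_idx.shape[0]
    actions = np.empty(n, dtype=np.int64)
    outcomes = np.empty(n, dtype=np.int64)
    q = np.zeros((8, 3))
    eps0, eps_rgo, eps_pnogo = _effective_rates(eps_hat, kappa, use_kappa)
    for t in range(n):
        c = cue_idx[t]
        v = valence_by_cue[c]
        pav = pi * (0.5 if v == 1 else -0.5)
        w0 = q[c, 0] + gobias + pav
        w1 = q[c, 1] + gobias + pav
        w2 = q[c, 2]
        m = max(w0, max(w1, w2))
        e0 = np.exp(w0 - m)
        e1 = np.exp(w1 - m)
        e2 = np.exp(w2 - m)
        z = e0 + e1 + e2
        u = np.random.random() * z
        if u < e0:
            a = 0
        elif u < e0 + e1:
            a = 1
        else:
            a = 2
        correct = a == req_action[c]
        favorable = correct == (valid[t] == 1)
        if v == 1:
            r = 1 if favorable else 0
        else:
            r = 0 if favorable else -1
        actions[t] = a
        outcomes[t] = r
        s = _scaled_outcome(r, v, rho_a, rho_b, outcome_mode)
        lr = _pick_rate(r, a, eps0, eps_rgo, eps_pnogo, use_kappa)
        q[c, a] += lr * (s - q[c, a])
    return actions, outcomes


@njit(cache=True)
def pgo_curves_kernel(cue_idx, valid, req_action, valence_by_cue,
                      rho_a, rho_b, eps_hat, gobias, pi, kappa,
                      outcome_mode, use_kappa, n_sims, seed):
    """Mean simulated P(Go) per (cue, within-cue presentation) over n_sims runs."""
    n = cue_idx.shape[0]
    go_count = np.zeros((8, n))  # presentation index per cue <= n
    pres_len = np.zeros(8, dtype=np.int64)
    for s_i in range(n_sims):
        actions, _ = simulate_kernel(
            cue_idx, valid, req_action, valence_by_cue,
            rho_a, rho_b, eps_hat, gobias, pi, kappa,
            outcome_mode, use_kappa, seed + s_i,
        )
        pres = np.zeros(8, dtype=np.int64)
        for t in range(n):
            c = cue_idx[t]
            if actions[t] != 2:
                go_count[c, pres[c]] += 1.0
            pres[c] += 1
        if s_i == 0:
            for c in range(8):
                pres_len[c] = pres[c]
    return go_count / n_sims, pres_len
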