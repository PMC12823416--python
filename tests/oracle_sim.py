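"""Independent brute-force two-scenario simulator.

Pure-Python reference implementation used only as a test oracle: plain
nested loops, no vectorization, no shared code with the library beyond the
input container. Recomputes the status-quo and counterfactual yearly GDP
paths directly from the model's recursions.
"""

import math


def _xi_table(inp, cap):
    T, A = inp.n_years, len(inp.ages)
    xi = [[0.0] * A for _ in range(T)]
    for t in range(T):
        for a in range(A):
            yll, yld = inp.yll[t][a], inp.yld[t][a]
            if yll > 0:
                xi[t][a] = yld / yll
            elif yld > 0:
                xi[t][a] = cap
    return xi


def _caregiver_weights(inp):
    A = len(inp.ages)
    w = [0.0] * A
    for a in range(A):
        for t in range(inp.n_years):
            for s in range(len(inp.sexes)):
                w[a] += inp.participation[t][a][s] * inp.population[t][a][s]
    tot = sum(w)
    return [v / tot for v in w]


def _human_capital_weight(inp, a, t, s):
    ys = inp.schooling[t][a][s]
    e = max(float(inp.ages[a]) - ys - 5.0, 0.0)
    return math.exp(inp.eta1 * ys + inp.eta2 * e + inp.eta3 * e * e)


def simulate_pair(inp, cfg):
    """Return (Y_status_quo, Y_counterfactual) as Python lists."""
    T, A, S = inp.n_years, len(inp.ages), len(inp.sexes)
    ch = cfg.channels
    xi = _xi_table(inp, cfg.xi_cap)
    w = _caregiver_weights(inp)
    sig = inp.all_cause_mortality
    sig_r = inp.diabetes_mortality
    n = inp.population

    # ---- informal care deductions per (year, age), spread over sexes
    def care_grid(scale):
        if not ch.informal_care or cfg.care_hours == 0 or scale == 0:
            return None
        grid = []
        for t in range(T):
            total = 0.0
            for a in range(A):
                total += inp.prevalence[t][a] * scale
            total *= cfg.care_hours / cfg.workweek
            grid.append([total * w[a] for a in range(A)])
        return grid

    def effective_H(pop, part, care):
        H = []
        for t in range(T):
            acc = 0.0
            for a in range(A):
                for s in range(S):
                    L = part[t][a][s] * pop[t][a][s]
                    if care is not None:
                        L -= care[t][a] / S
                        if L < 0:
                            L = 0.0
                    acc += _human_capital_weight(inp, a, t, s) * L
            H.append(acc)
        return H

    # ---- status quo
    H_sq = effective_H(n, inp.participation, care_grid(1.0))
    K_sq = [0.0] * T
    K_sq[0] = inp.capital0
    for t in range(T - 1):
        K_sq[t + 1] = (1.0 - inp.delta) * K_sq[t] + inp.saving_rate[t] * inp.gdp[t]
    A_tfp = [inp.gdp[t] / (K_sq[t] ** inp.alpha * H_sq[t] ** (1.0 - inp.alpha))
             for t in range(T)]
    Y_sq = [float(v) for v in inp.gdp]

    # ---- counterfactual population: direct recursion under split mortality
    rho_m = cfg.rho if ch.mortality else 0.0
    nbar = [[[0.0] * S for _ in range(A)] for _ in range(T)]
    for a in range(A):
        for s in range(S):
            nbar[0][a][s] = n[0][a][s]
    for t in range(1, T):
        for s in range(S):
            nbar[t][0][s] = n[t][0][s]
            for a in range(1, A - 1):
                so = 1.0 - (1.0 - sig[t - 1][a - 1][s]) / (1.0 - rho_m * sig_r[t - 1][a - 1][s])
                nbar[t][a][s] = (1.0 - so) * nbar[t - 1][a - 1][s]
            so_top = 1.0 - (1.0 - sig[t - 1][A - 1][s]) / (1.0 - rho_m * sig_r[t - 1][A - 1][s])
            so_pen = 1.0 - (1.0 - sig[t - 1][A - 2][s]) / (1.0 - rho_m * sig_r[t - 1][A - 2][s])
            nbar[t][A - 1][s] = ((1.0 - so_top) * nbar[t - 1][A - 1][s]
                                 + (1.0 - so_pen) * nbar[t - 1][A - 2][s])

    # ---- counterfactual participation: explicit history product
    lbar = [[[inp.participation[t][a][s] for s in range(S)] for a in range(A)]
            for t in range(T)]
    if ch.morbidity:
        for t in range(T):
            for a in range(A):
                for s in range(S):
                    prod = 1.0
                    for tau in range(min(t, a)):
                        f = ((cfg.p ** tau) * cfg.rho
                             * sig_r[t - 1 - tau][a - 1 - tau][s]
                             * xi[t - 1 - tau][a - 1 - tau])
                        prod *= 1.0 - f
                    v = inp.participation[t][a][s] / prod
                    lbar[t][a][s] = min(v, 1.0)

    H_cf = effective_H(nbar, lbar, care_grid(1.0 - cfg.rho))

    # ---- coupled counterfactual capital/output loop
    K = inp.capital0
    Y_cf = []
    for t in range(T):
        Y = A_tfp[t] * K ** inp.alpha * H_cf[t] ** (1.0 - inp.alpha)
        Y_cf.append(Y)
        tc = inp.treatment_cost[t] if ch.treatment_cost else 0.0
        sbar = (inp.saving_rate[t] * Y + cfg.rho * cfg.chi * tc) / Y
        sbar = min(sbar, 1.0)
        K = (1.0 - inp.delta) * K + sbar * Y
    return Y_sq, Y_cf
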