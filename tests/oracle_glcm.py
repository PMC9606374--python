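"""Naive double-loop reference implementation of the 19 GLCM features.

Kept deliberately independent of woundtherm.texture: plain Python loops over
all (i, j) level pairs, no vectorisation, no shared helpers.  Used by the
test suite as the oracle the fast implementation must match.
"""

import math


def naive_features(p, log_base="natural"):
    ng = len(p)
    log = math.log2 if log_base == "2" else math.log

    def xlogx(v):
        return v * log(v) if v > 0 else 0.0

    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    sd_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng)))
    sd_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng)))

    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_diff = {k: 0.0 for k in range(ng)}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] += p[i][j]
            p_diff[abs(i - j)] += p[i][j]

    eng = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
    cont = sum((i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    if sd_x == 0 or sd_y == 0:
        corr = 0.0
    else:
        corr = (
            sum((i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng))
            - mu_x * mu_y
        ) / (sd_x * sd_y)
    sum_sq = sum((i + 1 - mu_x) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    sum_av = sum(k * v for k, v in p_sum.items())
    sum_var = sum((k - sum_av) ** 2 * v for k, v in p_sum.items())
    entr = -sum(xlogx(p[i][j]) for i in range(ng) for j in range(ng))
    sum_ent = -sum(xlogx(v) for v in p_sum.values())
    diff_ent = -sum(xlogx(v) for v in p_diff.values())

    hx = -sum(xlogx(v) for v in px)
    hy = -sum(xlogx(v) for v in py)
    hxy1 = -sum(
        p[i][j] * log(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if p[i][j] > 0 and px[i] * py[j] > 0
    )
    im_corr = (entr - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0

    hom = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    a_corr = sum((i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng))
    d_sim = sum(abs(i - j) * p[i][j] for i in range(ng) for j in range(ng))
    cl_sha = sum(
        (i + j + 2 - mu_x - mu_y) ** 3 * p[i][j] for i in range(ng) for j in range(ng)
    )
    cl_pro = sum(
        (i + j + 2 - mu_x - mu_y) ** 4 * p[i][j] for i in range(ng) for j in range(ng)
    )
    max_prob = max(p[i][j] for i in range(ng) for j in range(ng))
    id_hom = sum(p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
    id_norm = sum(p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng))
    idm_norm = sum(
        p[i][j] / (1 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng)
    )

    return {
        "Eng": eng, "Cont": cont, "Corr": corr, "sumSq": sum_sq,
        "sumAv": sum_av, "sumVar": sum_var, "Entr": entr, "sumEnt": sum_ent,
        "diffEnt": diff_ent, "imCorr": im_corr, "Hom": hom, "aCorr": a_corr,
        "dSim": d_sim, "clSha": cl_sha, "clPro": cl_pro, "maxProb": max_prob,
        "idHom": id_hom, "idNorm": id_norm, "idmNorm": idm_norm,
    }
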