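"""Generate the frozen AUC-correlation lookup table.

For two diagnostic scores measured on the same cases, the z-test for the
difference of their AUCs needs r = Corr(AUC1_hat, AUC2_hat).  Under the
equal-AUC binormal model (positive scores N(delta, 1), negatives N(0, 1),
with within-class correlation rho between the two scores), r is estimated
here by Monte Carlo: many paired cohorts are simulated per (rho, A) cell and
the empirical correlation between the two AUC estimates is recorded, indexed
by the average measured within-class Spearman correlation.

Output: src/spchlpa/_hm_rtable.py
"""

import numpy as np
from scipy import stats

RHOS = np.arange(0.0, 1.0001, 0.1)
AUCS = np.array([0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 0.975])
N_POS = 60
N_NEG = 60
R = 3000


def auc_mw(pos, neg):
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return (ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) / (
        len(pos) * len(neg)
    )


def cell(rho, A, rng):
    delta = np.sqrt(2.0) * stats.norm.ppf(A)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    L = np.linalg.cholesky(cov)
    a1 = np.empty(R)
    a2 = np.empty(R)
    sp = np.empty(R)
    for r in range(R):
        pos = rng.standard_normal((N_POS, 2)) @ L.T + delta
        neg = rng.standard_normal((N_NEG, 2)) @ L.T
        a1[r] = auc_mw(pos[:, 0], neg[:, 0])
        a2[r] = auc_mw(pos[:, 1], neg[:, 1])
        sp_pos = stats.spearmanr(pos[:, 0], pos[:, 1]).statistic
        sp_neg = stats.spearmanr(neg[:, 0], neg[:, 1]).statistic
        sp[r] = 0.5 * (sp_pos + sp_neg)
    if a1.std() == 0 or a2.std() == 0:
        rr = 1.0 if rho == 1.0 else 0.0
    else:
        rr = float(np.corrcoef(a1, a2)[0, 1])
    return rr, float(sp.mean())


def main():
    rng = np.random.default_rng(20210927)
    table = np.zeros((len(RHOS), len(AUCS)))
    rowcoord = np.zeros((len(RHOS), len(AUCS)))
    for i, rho in enumerate(RHOS):
        for j, A in enumerate(AUCS):
            if rho == 1.0:
                table[i, j] = 1.0
                rowcoord[i, j] = 1.0
                continue
            rr, sp = cell(rho, A, rng)
            table[i, j] = rr
            rowcoord[i, j] = sp
            print(f"rho={rho:.2f} A={A:.3f} -> r={rr:.3f} (spearman {sp:.3f})")
    # row coordinate: mean measured Spearman per rho, shared across columns
    rows = rowcoord.mean(axis=1)
    rows[0] = 0.0
    rows[-1] = 1.0
    table[0, :] = 0.0
    # enforce monotone non-decreasing r along the rank-correlation axis
    table = np.maximum.accumulate(np.clip(table, 0.0, 1.0), axis=0)
    # strictify ties introduced by clipping/accumulation
    for j in range(table.shape[1]):
        for i in range(1, table.shape[0]):
            if table[i, j] <= table[i - 1, j]:
                table[i, j] = table[i - 1, j] + 1e-6

    with open("src/spchlpa/_hm_rtable.py", "w") as fh:
        fh.write('"""Frozen lookup table for the correlated-AUC z-test.\n\n')
        fh.write(
            "r = Corr(AUC1_hat, AUC2_hat) tabulated against the average\n"
            "within-class rank correlation of the two score sets (rows) and\n"
            "the average AUC (columns), computed once by Monte Carlo under\n"
            "the equal-AUC binormal ROC model (synthetic reconstruction).\n"
            '"""\n\nimport numpy as np\n\n'
        )
        fh.write(
            "RANK_CORR_GRID = np.array(%s)\n\n"
            % np.array2string(rows, separator=", ", precision=4)
        )
        fh.write(
            "AUC_GRID = np.array(%s)\n\n"
            % np.array2string(AUCS, separator=", ", precision=4)
        )
        fh.write(
            "R_TABLE = np.array(\n%s\n)\n"
            % np.array2string(table, separator=", ", precision=4)
        )
    print("written src/spchlpa/_hm_rtable.py")


if __name__ == "__main__":
    main()
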