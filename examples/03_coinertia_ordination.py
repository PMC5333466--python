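"""Ordinations: NSCA, unsupervised co-inertia, BGA and the supervised axis.

The expression and motif tables are linked over genes; co-inertia finds the
axes on which their gene scores co-vary most, and the supervised run
reduces the expression side to one resistant-vs-parental contrast.
"""

import tfcia as t
from tfcia.ordination import bga, coinertia, nsca, rv_permutation_test, supervised_cia

tables, expr, _, truth = t.simulate_all(t.SimulationConfig(seed=1))
norm = t.quantile_normalize(expr)

ord_expr = nsca(norm.values, centering="uniform")
ord_motif = nsca(tables[-1].counts, centering="uniform")
print(f"expression NSCA total inertia: {ord_expr.total_inertia:.3e}")
print(f"motif NSCA (threshold 0.85) total inertia: {ord_motif.total_inertia:.3e}")

cia = coinertia(ord_expr, ord_motif)
rv, p, _ = rv_permutation_test(ord_expr, ord_motif, 199, rng=1)
print(f"unsupervised co-inertia: RV = {cia.rv:.4f}, "
      f"row-permutation p = {p:.3f} (planted coupling is detectable)")

res = bga(norm.values, norm.group_of)
print(f"BGA on 3 groups: {res.n_axes} axes (= K-1), "
      f"between/total inertia = {res.between_ratio:.3f}")

sup = supervised_cia(norm.values, norm.group_of, tables[-1].counts, ("Ag", "D8"))
top = sup.motif_loadings.sort_values(ascending=False).head(5)
print("top motifs on the resistance-oriented axis (Ag vs D8):")
for motif, loading in top.items():
    mark = " <- planted" if motif in truth.active_motifs else ""
    print(f"  {motif}: {loading:+.3e}{mark}")
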