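"""How many distinct ROC curves share one AUC value?

Counts lattice ROC curves per AUC deficit for 5 cases and 6 controls and
shows the exact Mann–Whitney null (every interleaving equally likely when
the case and control score distributions coincide).
"""

from exactroc import count_roc_curves, count_table, mann_whitney_null

n, m = 5, 6
print(f"k_4 = {count_roc_curves(4, n, m)} distinct ROC curves attain "
      f"AUC = 26/30 (deficit 4)")

table = count_table(n, m)
null = mann_whitney_null(n, m)
print(f"\n{'deficit':>8} {'auc':>8} {'k_i':>6} {'P(F=G)':>10}")
for i in (0, 1, 2, 4, 10, 15):
    print(f"{i:>8} {n * m - i:>5}/30 {table[i]:>6} {null[i]:>10.5f}")
print(f"\nsum of counts = {sum(table.counts)} = binomial(11, 5); "
      f"probabilities sum to {sum(null):.6f}")
# Under F = G each curve has probability n!m!/(n+m)! = 1/462, so the
# deficit-4 probability is k_4/462 = 5/462.
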