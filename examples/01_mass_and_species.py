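"""Exact masses and the impurity ledger for a modified oligonucleotide.

Parses a 2'-MOE/DNA gapmer with a phosphorothioate backbone, prints its
formula and masses, and the table of theoretical species an impurity
report would be matched against.
"""

from olims import build_impurity_table, parse_sequence

# 5-10-5 gapmer: MOE wings ('e' prefix, 5mC in the wings), deoxy core,
# all linkages phosphorothioate ('*')
notation = "eG*eA*e5mC*eU*eU*dC*dA*dT*dG*dA*dC*dT*dG*dC*dA*eU*eG*e5mC*eA*eG"
seq = parse_sequence(notation, name="gapmer-demo")

comp = seq.composition()
print(f"sequence      : {notation}")
print(f"length        : {len(seq)} nt, {seq.n_ps_linkages} PS linkages")
print(f"formula       : {comp.hill_formula()}")
print(f"monoisotopic  : {seq.monoisotopic_mass():.6f} Da")
print(f"average       : {seq.average_mass():.4f} Da")
print()
print("impurity table (hexylamine/HFIP mobile phase):")
print(build_impurity_table(seq).to_string(index=False, float_format="%.6f"))
print()
print("Each row is a neutral-mass target: the full-length product (FLP),")
print("1-3 hexylamine adducts, loss of each nucleobase present, and the")
print("PO impurity (one backbone sulfur replaced by oxygen, -15.977 Da).")
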