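"""The seven peptide properties, plus a SILAC heavy-lysine mass
override loaded from XML."""

from seqforge.protein import (
    aa_composition,
    aliphatic_index,
    extinction_coefficient,
    gravy,
    instability_index,
    isoelectric_point,
    load_residue_overrides,
    molecular_weight,
)

peptide = "MKWVTFISLLLLFSSAYSRGV"  # serum albumin signal peptide region

print(f"peptide: {peptide}")
print(f"  molecular weight (avg):  {molecular_weight(peptide):.4f} Da")
print(f"  molecular weight (mono): {molecular_weight(peptide, 'monoisotopic'):.4f} Da")
print(f"  isoelectric point:       {isoelectric_point(peptide):.2f}")
print(f"  GRAVY:                   {gravy(peptide):.3f}")
print(f"  instability index:       {instability_index(peptide):.2f}")
print(f"  aliphatic index:         {aliphatic_index(peptide):.2f}")
print(f"  extinction (reduced):    {extinction_coefficient(peptide)} /M/cm")
top = sorted(aa_composition(peptide).items(), key=lambda kv: -kv[1])[:3]
print(f"  most frequent residues:  {top}")

# Isotope label: SILAC K8 replaces every lysine mass (+8.0142 Da each).
k8 = load_residue_overrides(
    '<modifications>'
    '<modification name="Lys8" target="K" '
    'average="136.1883" monoisotopic="136.10916"/>'
    '</modifications>'
)
heavy = molecular_weight(peptide, overrides=k8)
print(f"  with SILAC K8 label:     {heavy:.4f} Da "
      f"(+{heavy - molecular_weight(peptide):.4f})")
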