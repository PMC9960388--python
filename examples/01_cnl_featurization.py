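"""Encode one MS/MS spectrum as ternary cumulative-neutral-loss features.

A spectrum's neutral losses (precursor minus fragment masses) are mapped
onto a 0-1000 Da grid with 0.01 Da bins: 1 = loss observed, 0 = loss
absent but possible, -1 = loss heavier than the precursor (impossible).
"""

from cnlri import CNLGrid, Spectrum, compute_cnls, encode_row

# a 300 Da precursor losing water (18.011), C4H8 (56.063) and SO2 (65.97)
spectrum = Spectrum(
    spectrum_id="demo",
    precursor_mz=300.0,
    fragments=((234.03, 55.0), (243.937, 12.0), (281.989, 100.0), (300.0, 40.0)),
)

losses = compute_cnls(spectrum)
print(f"neutral losses (Da): {[round(l, 3) for l in losses.losses]}")

row = encode_row(losses, CNLGrid())
print(f"bins set to 1: {row.one_bins}")
print(f"first impossible bin: {row.neg_start} (center {row.neg_start * 0.01:.2f} Da)")

vector = row.vector
print(f"vector length: {vector.size}")
print(f"counts: +1={int((vector == 1).sum())}, 0={int((vector == 0).sum())}, "
      f"-1={int((vector == -1).sum())}")
# the +1 bins are the observed losses at 0.01 Da resolution; every bin whose
# center exceeds the 300 Da precursor is impossible and encoded -1.
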