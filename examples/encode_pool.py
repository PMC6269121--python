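"""Encode peptides as PresentER minigene oligos and QC the pool.

Each peptide becomes: 5' adapter + SfiI site + signal-sequence CDS +
epitope DNA + stop + SfiI site + 3' adapter. The epitope DNA is the
sequencing barcode, so encodings must be unique and the only SfiI sites
must be the cloning flanks.
"""

import presenter as ps
from presenter.encoding import digest_sfii

peptides = ["SIINFEKL", "SNFVFAGI", "SNFVSAGI", "VTFVFAGL", "EQYKFYSV"]
pool = ps.build_pool(peptides, seed=1)

mg = pool.minigenes[0]
print(f"{mg.peptide}: oligo {len(mg.oligo)} nt, epitope {mg.epitope_dna}")
frags = digest_sfii(mg.oligo)
print(f"SfiI digestion yields {len(frags)} fragments; "
      f"insert released intact: {mg.full_insert in frags[1]}")

qc = ps.validate_pool(pool)
print(f"\npool QC: {qc.n_minigenes} minigenes, "
      f"{len(qc.duplicate_epitopes)} duplicate encodings, "
      f"{len(qc.oligos_with_wrong_sfii_count)} oligos with stray SfiI sites, "
      f"min pairwise Hamming distance {qc.min_pairwise_hamming}")
# A minimum pairwise distance >= 2 means a single sequencing error can
# never convert one barcode into another.
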