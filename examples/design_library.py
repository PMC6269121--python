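"""Design a wild-type / single-mutant MHC-I 8-mer library from a proteome.

Builds a synthetic proteome, scores every unique 8-mer with the bundled
toy affinity model, samples a wild-type library of binders (IC50 < 500
nM), derives one binding-competent single-residue mutant per member, and
prints the characterisation statistics: where the mutations land, how the
predicted affinity shifts, and which residue classes interconvert.
"""

import presenter as ps

proteome = ps.simulate_proteome(n_proteins=40, length=300, seed=7)
model = ps.toy_model(seed=8)

kmers = ps.enumerate_kmers(proteome, k=8)
ic50 = ps.predict_ic50_many(list(kmers), model)
print(f"{len(kmers)} unique 8-mers, {(ic50 < 500).sum()} predicted binders (<500 nM)")

config = ps.LibraryDesignConfig(k=8, n_select=500, seed=9)
wildtype = ps.select_wildtype_library(kmers, ic50.to_dict(), config)

cache = ic50.to_dict()
ic50_of = lambda p: cache.setdefault(p, ps.predict_ic50(p, model))
mutants, unmutable = ps.build_mutant_library(wildtype, set(kmers), ic50_of, config)
library = ps.add_controls(wildtype)
print(f"wild-type library: {len(wildtype)}; mutants: {len(mutants)} "
      f"({len(unmutable)} unmutable); with controls: {len(library)}")

char = ps.characterize_library(wildtype, mutants)
print(f"\nmutants within 100 nM of their wild-type partner: "
      f"{char.fraction_within_100nM:.1%}")
print("\nmutated-position histogram (1-based):")
print(char.position_histogram.to_string())
print("\nresidue-class substitution matrix (rows: from, cols: to):")
print(char.substitution_class_matrix.to_string())
# Each mutant differs from its partner at exactly one position and never
# recreates a proteome 8-mer, so every mutant is a genuine neo-epitope
# candidate that still binds MHC-I.
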