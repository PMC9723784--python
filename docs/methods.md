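# Methods

## Model and procedure

The pipeline transfers enzyme–substrate knowledge across a chemical
similarity relation. The underlying assumption is the classical
similar-property principle of cheminformatics: molecules with highly
overlapping 2-D substructure fingerprints are more likely to be accepted
by the same enzyme. Stages, in order:

1. **Parsing.** Each compound's SMILES is parsed into a molecular graph
   (atoms with element, aromaticity, charge, hydrogen counts; bonds with
   order). The parser covers the organic subset B, C, N, O, P, S, F, Cl,
   Br, I, aromatic lowercase atoms, branches, ring closures (digits and
   `%nn`), bracket atoms with charge and explicit H. Stereo markers and
   isotopes are accepted and discarded — the analysis is 2-D. Wildcards
   and multi-component input are rejected (an opt-in largest-component
   mode keeps the biggest fragment). Every parse is validated: connected
   graph, paired ring closures, per-atom valence.
2. **Fingerprinting.** See below.
3. **Similarity matrix.** All PDCC × LDCC Tanimoto coefficients,
   T = |A∩B| / |A∪B| on the fingerprints' bit sets.
4. **Thresholding.** Pairs with T ≥ θ become similarity edges. θ defaults
   to 0.65. Thresholding is applied to the unrounded fraction;
   percentages are presentation only. The inclusive `≥` is the default
   because the edge rule is stated as "greater than or equal"; a strict
   `>` variant is exposed as a flag.
5. **Graph.** Undirected tripartite graph over PDCC, LDCC and enzyme
   nodes; similarity edges only PDCC–LDCC, catalysis edges only
   LDCC–enzyme. Graph semantics are unweighted (no weighted graph
   algorithm is used anywhere); the similarity fraction is kept as an
   edge attribute because ranking predictions and exporting a legible
   network costs nothing and loses nothing. A PDCC may connect to *all*
   LDCC above θ, not only its single best match — the multi-neighbor
   case-(ii) motif requires it; a `top_k` option restricts each PDCC to
   its k best LDCC for users wanting the stricter reading. PDCC with no
   edge above θ are dropped from the graph by default and listed in the
   run manifest.
6. **Cases and predictions.** Each PDCC is labelled by motif
   (case i / ii / iii-member / unclassified, as a *set* — motifs
   overlap). Predicted enzymes are those one similarity edge plus one
   catalysis edge away, one prediction per enzyme supported by its
   highest-similarity LDCC, ranked by that similarity with lexicographic
   enzyme-id tie-breaks. Enzyme nodes carry per-genome gene counts so a
   prediction names the genomes encoding it.

## Fingerprint schemes

Two self-contained schemes are specified down to the hash so any
re-implementation is bit-compatible; both hash feature strings with
FNV-1a 64-bit over UTF-8 and set bit `hash mod n_bits` (default
n_bits = 2048):

- **path** — all simple linear paths of 1..7 bonds, serialized as
  alternating atom tokens (element, lowercased when aromatic, charge
  suffix when charged) and bond tokens (`- = # :`); each path is read in
  both directions and the lexicographically smaller string is the
  feature; one bit per distinct path, no per-feature folding. Single-atom
  molecules are an *error* under this scheme rather than an empty
  fingerprint — an empty fingerprint would silently zero every Tanimoto
  in a matrix.
- **morgan** — ECFP-style: round-0 atom identifiers hash (element,
  degree, formal charge, aromatic flag, implicit-H count); each round
  r = 1..radius (default 2) rehashes the atom's previous identifier with
  the sorted (bond token, neighbor identifier) pairs; identifiers from
  every round set bits, with no duplicate-environment suppression
  (collisions only blur, never bias).

Two adapter schemes delegate to RDKit when installed: **toolkit_default**
(RDKit's topological fingerprint, `n_bits` honored) and **maccs** (the
166-bit MACCS structural keys). MACCS is the *literature-compatibility*
backend: across the flagship lignin/plastic compound pairs, the MACCS
keys reproduce the reported percentages (monomethyl
phthalate–vanillate ≈ 70%; terephthalic acid above the 65% threshold
against both benzoate and cis,cis-muconate), whereas the topological
default does not place the aromatic/aliphatic pair terephthalate–muconate
above any plausible threshold. Small, heteroatom-rich acids are exactly
the regime where dense structural keys behave differently from sparse
hashed-path fingerprints, and the reported numbers discriminate clearly
between the two; the package keeps the scheme a configuration choice and
uses `maccs` wherever reported values are being compared.

## Valence model

Implicit hydrogens come from smallest-feasible default valences
(B 3; C 4; N 3; O 2; P 3/5; S 2/4/6; halogens 1), shifted by the formal
charge's sign. Aromatic bonds count 1.5 toward an atom's bond-order sum,
with two refinements: ties of x.5 round *down* (so a ring-fusion aromatic
carbon with three aromatic bonds totals 4, not 5), and aromatic bonds on
lone-pair-donating aromatic heteroatoms — `o`, `s`, and `[nH]`-type
nitrogen — count 1 (these atoms have two sigma ring bonds and donate a
lone pair to the π system; a uniform 1.5 rule would wrongly reject furan,
thiophene and pyrrole). Bracket atoms carry exactly the hydrogens they
declare (zero when none declared), matching SMILES semantics; radicals
are outside the model, so `[13C]CO` is a valence error while `[13CH3]CO`
parses.

Aromatization is deliberately minimal: lowercase input is trusted, and
additionally every 6-membered all-carbon ring with alternating
single/double bonds is relabelled aromatic, so Kekulé and aromatic
spellings of benzenoids fingerprint identically. No general Hückel
perception is attempted — the compound classes in scope (benzenoid
aromatics and small aliphatic acids) do not need it, and the restricted
rule is exactly testable.

## Input contracts

Three TSV tables (UTF-8, tab-delimited, `#` comments): the compound
catalog (id, name, smiles, partition ∈ {LDCC, PDCC} [, xref]), the
enzyme–substrate map (id, name, ec, ko, comma-separated LDCC substrate
ids), and per-genome gene counts (genome_id, enzyme_id, gene_count ≥ 0).
Loaders run strict (any bad row aborts with a per-row report) or lenient
(bad rows dropped with warnings); duplicate ids are always fatal; an
enzyme whose substrates all fail to resolve to LDCC is invalid. Enzymes
are keyed by a local id with EC and KO numbers as annotations, because
real curation mixes EC numbers, gene names and KO identifiers.

The packaged catalog contains the flagship compounds and enzymes of
lignin-assisted plastic catabolism, with SMILES transcribed from each compound's standard
structure and cross-checked against PubChem by name. The packaged
per-genome gene counts are a **synthetic illustrative stand-in**
(`genome_counts_synthetic.tsv`), not measured annotation counts. At θ = 0.65 under MACCS the fixture
reproduces the case-(i) motif for monomethyl phthalate and the case-(ii)
motif for 3,4-dihydroxyphthalate; the two hydroxyalkanoates stay below
threshold against every packaged (aromatic) LDCC, so the case-(iii)
motif is exercised by constructed motifs and the synthetic benchmark
instead.

## Synthetic benchmark

The generator emulates the *shape* of the real inputs — compound families
with high within-family and low cross-family similarity, an enzyme per
family acting on the family's LDCC, small integer gene counts — with
known ground truth. Four scaffolds (benzene, phenol, a C4 carboxylic
chain, furan), each with three substitution slots independently decorated
(probability = `decoration_rate`, default 0.3) from five substituents
(methyl, hydroxyl, carboxyl, methoxy, amino); duplicates are resampled
under a bounded retry budget and every product must parse. Defaults: 4
families × (4 LDCC + 4 PDCC), three synthetic genomes with per-enzyme
gene counts uniform on 1..4. All draws flow through a single seeded
`numpy.random.Generator` (PCG64) in fixed order, so identical
(params, seed) regenerate byte-identical tables on any platform.

What the generator does *not* emulate: chemically realistic enzyme
specificity (family membership is purely structural), reaction chemistry,
polymers, or the size and diversity of real compound catalogs. Passing
the recovery test therefore demonstrates that the pipeline's machinery —
fingerprints, matrix, threshold, graph, ranking — correctly propagates a
structural signal to enzyme predictions; it does not validate the
biochemical hypothesis on real compounds.

On the default benchmark at seed 0 with path fingerprints and θ = 0.65,
top-1 enzyme recovery is 0.5 (8 of 16 PDCC have no LDCC above threshold
and count as failures). This value is pinned by an independent
brute-force nearest-neighbor oracle and frozen as a regression test; the
interesting property is its exact reproducibility and its agreement with
the oracle, not its magnitude — at θ = 0.65 many legitimately decorated
family members fall below threshold, exactly as isolated PDCC do on real
catalogs.

## Numerical and degenerate-input choices

- Two empty fingerprints give Tanimoto 0.0 with a warning (the common
  toolkit convention) rather than NaN or 1.
- Similarity values are validated into [0, 1] at matrix construction.
- Matrix export uses 4-decimal cells; thresholding always happens on the
  unrounded values before export.
- Deterministic orderings throughout: row-major edge lists, lexicographic
  node insertion, similarity-then-id prediction ranking. Two runs on
  identical inputs are byte-identical (the manifest's timestamp is the
  single exception, and it lives only in the manifest).
- GraphML serializes per-genome counts as `genome:count;...` strings
  (GraphML attributes are scalar); import restores the mapping and
  re-checks tripartiteness.

## Problem sizes

The packaged catalog is 5 × 7 compounds; the default synthetic benchmark
is 32 compounds across 4 families; the matrix-shape check runs one
113-compound catalog (43 × 70). These sizes keep the full suite and the
acceptance script comfortably interactive while exercising every code
path at full catalog scale (43 x 70) for the matrix stage.

## Known limitations

- The SMILES subset excludes radicals, dative/ionic multi-fragment salts,
  general Hückel aromaticity, stereochemistry and isotope semantics.
- Fingerprint-based transfer cannot distinguish positional isomers that
  share most substructures; MACCS keys in particular saturate for small
  acids (high baseline similarity).
- The ≥65% threshold is a single global cut; no per-pair significance or
  null model is computed.
- Predictions are hypotheses for experimental triage, not activity
  claims.
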