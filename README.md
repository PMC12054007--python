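# hdrakit

Domain-architecture survey tooling for soluble heterodisulfide reductase
subunit A (**HdrA**), the flavin-carrying subunit that performs
flavin-based electron bifurcation (FBEB) and confurcation (FBEC) in
methane- and alkane-metabolizing archaea.

## What it does, and for whom

HdrA couples the oxidation of a mid-potential electron donor (H₂, F₄₂₀H₂,
formate, or NADH) to the simultaneous reduction of the high-potential
heterodisulfide CoM-S-S-CoB and the low-potential carrier ferredoxin.
The protein family is highly modular: members differ in the number and
placement of iron-sulfur cluster domains, in fused MvhD subunits, in
duplicated thioredoxin reductase modules, and in inserted GltD (glutamate
synthase small subunit) domains.  `hdrakit` is for microbiologists and
comparative genomicists who want to:

1. **Scan** protein sequences for the conserved fingerprints of the
   family — the 4-cysteine [4Fe-4S] motif `C-X2-C-X2-C-X3-C`, the paired
   `C-X2-C` half-sites of [2Fe-2S] MvhD, and the glycine-rich Rossmann
   fingerprints `G-X-G-X-X-G` (NAD⁺-preferring) vs `G-X-G-X-X-A`
   (NADP⁺-preferring) — and assemble them into an ordered domain
   architecture.  Externally computed conserved-domain hit tables
   (CD-Search style TSV) can be supplied and take precedence.
2. **Classify** each architecture into one of 28 classes grouped into 4
   major types (after a 300-residue quality filter):
   type **II** has two thioredoxin reductase (TRX_FAD) domains, type
   **III** an inserted GltD, type **Ia** a C-terminal MvhD fusion, and
   type **I** is the canonical single-TRX form.
3. **Call key residues** by global alignment to a reference frame: the
   FAD-stabilising lysine/glutamate pair (positions 409/356 in the
   reference frame) whose joint presence marks bifurcation competence,
   and the Molybdop active-site frame (Cys118 / Pro234 / Phe235) that
   distinguishes catalytic molybdopterin enzymes from non-catalytic
   structural subunits with an occluded Mo/W-bisPGD site.
4. **Prepare phylogeny inputs**: 80%-identity greedy clustering to
   representatives, splitting two-TRX proteins into N/C halves, excising
   inserted GltD domains, and extracting conserved core columns from an
   alignment by per-column Shannon entropy and gap fraction (or by a
   reference segment mask).
5. **Detect hdrA gene clusters** in feature tables by transcription
   direction and intergenic gap (≤200 nt by default), and **infer the
   FBEB/FBEC reaction** of the encoded complex from cluster composition
   through an editable most-specific-first rulebook.

A first-class synthetic-data generator (`hdrakit.synth`) produces
proteins with planted architectures and residue states, gene
neighborhoods with planted cluster layouts, and alignment fixtures with
known core/insert columns, so the entire pipeline is testable without
any downloads.

## Worked example

```bash
hdrakit simulate --classes A1,A3,A9 --n-per-class 2 --seed 0 --outdir demo
hdrakit classify --fasta demo/proteins.fasta --out demo/classes.tsv
head -4 demo/classes.tsv
```

prints

```
# min_length=300
protein_id	filter_status	class_name	major_type	architecture	evidence
A1_0_000	passed	A1	I	FeS_N TRX_FAD TRX_FeS Fd_ins Fd_C	FeS_N TRX_FAD TRX_FeS Fd_ins Fd_C
A1_0_001	passed	A1	I	FeS_N TRX_FAD TRX_FeS Fd_ins Fd_C	FeS_N TRX_FAD TRX_FeS Fd_ins Fd_C
```

i.e. both simulated A1 proteins pass the 300-aa filter and are recovered
as class A1 (major type I) with the canonical five-domain architecture:
N-terminal iron-sulfur domain, thioredoxin reductase FAD and iron-sulfur
domains, inserted ferredoxin, C-terminal ferredoxin.  Running the
neighborhood stage on the bundled simulated contig,

```bash
hdrakit neighborhood --features demo/neighborhood.gff3 \
    --out-clusters demo/clusters.tsv --out-predictions demo/pred.tsv
head -3 demo/pred.tsv
```

prints

```
# max_gap=200 same_strand_required=True
cluster_id	hdrA_types	mid_potential_carrier	high_potential_arm	low_potential_arm	confidence	fired_rules	notes
synthetic_contig_1:0-8610	.	H2	CoM-S-S-CoB via HdrBC	Fd	validated	mid_h2,high_hdrbc,low_fd	.
```

— an *hdrA-hdrB-hdrC-mvhA-mvhG-mvhD* cluster is read as the
experimentally validated H₂-driven bifurcation: electrons from H₂ split
between CoM-S-S-CoB (via HdrBC) and ferredoxin.

The full pipeline (`hdrakit run --config config.yaml`) chains
scan → classify → residues → neighborhood, writing one TSV per stage and
a manifest; reruns from the same config are byte-identical.

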