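# omscaffold

Optical-mapping (OM) super-scaffolding for draft genome assemblies.

Short-read assemblies stall at repeats and leave genomes in hundreds of
scaffolds — too fragmented for chromosome-level analyses such as
rearrangement or sex-chromosome studies. Optical mapping images ordered
restriction-fragment patterns of individual, hundreds-of-kb DNA
molecules and so provides long-range evidence that joins scaffolds
without adding a single base. `omscaffold` implements that workflow as a
library and CLI for people improving assemblies with OM data (or
studying OM algorithms on simulated data):

1. **Enzyme evaluation** — in silico digest of the draft with candidate
   enzymes, scored by usable-fragment percentages, average/maximum
   fragment size and the count of fragments > 100 kb.
2. **Molecule simulation** — single-molecule restriction maps (SMRMs)
   with a configurable noise model (missed cuts, false cuts,
   multiplicative sizing error, desorption limit) and a ≥ 250 kb
   retention filter; or ingest real molecules from a simple tab-separated
   Rmap format.
3. **Map-to-map alignment** — an exact overlap dynamic program over
   fragment blocks, scoring a block of *t* vs *s* fragments with summed
   lengths *x*, *y* as
   `c_match − (x−y)²/(v_size·(x+y)) − c_cut·((t−1)+(s−1))`.
4. **Iterative extension** — molecules recruited to each scaffold's in
   silico seed map extend it beyond the scaffold ends by consensus
   (four iterations by default, low-coverage fringes trimmed).
5. **Super-scaffolding** — pairwise alignment of extended maps yields
   join candidates; greedy conflict resolution (each scaffold end used
   once, no cycles) produces super-scaffolds, emitted as gapped FASTA
   plus AGP v2.1 with a constant 600 N spacer between members.
6. **FISH anchoring** — cytogenetically ranked markers order and orient
   super-scaffolds along a chromosome into a pseudo-chromosome.

See `docs/methods.md` for the models, defaults and design decisions.

## Worked example

Build a small synthetic genome (1.5 Mb, four scaffolds cut from one
chromosome) and run the stages:

```sh
omscaffold stats demo.fasta
```
```
Assembly    Scaffold N50  Scaffold N90  N%    Total size  Scaffolds  To 90%
demo.fasta  372.58 kb     300.11 kb     0.06  1416.02 kb  4          4
```

The N50/N90 columns are the usual contiguity statistics; "To 90%" is the
number of largest scaffolds covering 90% of the assembly.

```sh
omscaffold evaluate-enzymes demo.fasta --enzymes KpnI,BamHI,AflII
```
```
enzyme  usable_pct_5_20  usable_pct_6_12  usable_pct_6_15  frags_gt_100kb  avg_frag_kb  max_frag_kb
KpnI    53.57            30.71            40.00            0               10.11        58.49
BamHI   27.13            15.96            17.29            0               3.77         20.77
AflII   28.10            17.08            19.83            0               3.90         42.46
```

KpnI's ~10 kb average fragment sits in the imageable sweet spot, which is
why it wins here (and won for the real bird genome this workflow was
built around).

```sh
omscaffold simulate demo_chrom.fasta --seed 11 --coverage 40 -o demo_mols.rmap --truth
omscaffold summarize demo_mols.rmap
```
```
                                           All     Maps of >250 kb
Total size                            79.62 Mb            60.10 Mb
Number of molecules                        258                 159
Average molecule size                308.59 kb           378.00 kb
Minimum molecule size                150.72 kb           251.75 kb
Average fragment size                13.060 kb           13.077 kb
```

```sh
omscaffold scaffold demo.fasta demo_mols.rmap --out-prefix demo_out
```
```
3/3 joins accepted; 1 super-scaffolds written to demo_out.fasta
```

All three true scaffold adjacencies are recovered; the four scaffolds
collapse into one super-scaffold whose AGP records members, orientations
and the 600 N gaps:

```
##agp-version	2.1
super001	1	377714	1	W	scaf01	1	377714	+
super001	377715	378314	2	N	600	scaffold	yes	map
super001	378315	743924	3	W	scaf02	1	365610	-
```

With FISH markers (5-column TSV: marker, chromosome, rank, scaffold,
position_bp) the `anchor` subcommand orders and orients super-scaffolds
into a pseudo-chromosome; `omscaffold run` drives all stages at once from
a YAML config. Every stage is also available as a plain Python function
(`omscaffold.digest`, `.simulate`, `.align`, `.extend`, `.superscaffold`,
`.anchor`).

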