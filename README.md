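# mapbench

Read-mapping benchmarks are only as good as their ground truth. `mapbench`
is a toolkit for building and scoring such benchmarks on platforms whose
errors are dominated by short indels in homopolymer runs (ion semiconductor
and pyrosequencing chemistry): it simulates single-end reads with controlled
insertion/deletion/substitution rates and *exact* per-read truth, classifies
mapper output under a stringent correctness definition, and scores repeat
recovery and variant-discovery accuracy against generated truth tables.

It is aimed at people who evaluate or tune mappers and variant-calling
pipelines: every generator emits machine-readable truth (TSV + read-name
codec), every evaluator consumes standard formats (SAM, VCF, FASTA/FASTQ),
and every run is reproducible from a single seed.

## The correctness definition

A simulated read is **correctly mapped** iff at least one reported hit
(primary, secondary or supplementary) satisfies, against the read's truth:

* same contig and strand;
* start and end positions recovered, and
* exactly the same number of insertions, deletions and substitutions.

Indels inside a homopolymer that touches an alignment end are invisible to a
mapper — the observed start/end simply shift. A per-end *shift* allowance
`s` (default 5) reconciles them: a start offset `d_L = start_hit −
start_true ≥ 0` is re-counted as `d_L` missing deletions, clipped read bases
as missing insertions, and the hit is correct iff, per end, the absorbed
shift is at most `s` and

```
del_hit + d_L + d_R = del_true,   ins_hit + clip_L + clip_R = ins_true,
sub_hit = sub_true  (no allowance).
```

Reads are then tallied as TP (correct), FP (incorrect, including random
reads that map anywhere) and FN (unmapped), giving

```
precision = TP/(TP+FP),  recall = TP/(TP+FN),  F = 2PR/(P+R).
```

Ground truth itself is *canonical*: each read is re-aligned against its
source window (unit costs, free end gaps on the reference side, fewest
substitutions among minimal-cost alignments, leftmost indels), so
compensatory injections (delete a base, reinsert the same base) never
inflate the truth counts.

Variant discovery is scored as CM (correctly identified mutations: same
kind and same or equivalent — i.e. left-normalized — position), IM
(incorrect) and NM (not found), with `precision = CM/(CM+IM)` and
`recall = CM/(CM+IM+NM)`.

## Worked example

```sh
mapbench make-fixtures --out fx --reads-per-file 40
mapbench eval-map --sam fx/perfect.sam --truth fx/grid_4.truth.tsv \
    --shift 5 --report report.json
```

prints

```json
{
  "TP": 38,
  "FP": 0,
  "FN": 0,
  "precision": 1.0,
  "recall": 1.0,
  "f_measure": 1.0,
  "fraction_mapped": 0.95,
  "categories": {
    "CORRECT": 38,
    "INCORRECT": 0,
    "UNMAPPED": 0,
    "RANDOM_REJECTED": 2,
    "RANDOM_MAPPED": 0
  },
  "shift": 5,
  "random_policy": "exclude_random"
}
```

`perfect.sam` is the alignment an ideal mapper would produce from the truth
table, so all 38 non-random reads classify CORRECT (precision = recall =
F-measure = 1) and only the 2 random reads — pure uniform sequence,
unmappable by construction — stay unmapped, giving `fraction_mapped 0.95`.
Feeding a real mapper's SAM instead shows how far it falls from that
ceiling. The other subcommands follow the same pattern: `simulate`
(FASTQ + truth TSV), `mutate` and `repeatgen` (benchmark references +
truth), `eval-repeats` (distinct-copy recovery histogram) and
`eval-variants` (CM/IM/NM scoring of a filtered VCF).

### Read-name codec

Each simulated read carries its truth in its name (SAM-safe, underscore
delimited, fixed field order):

```
<read_id>_<contig>_<start>_<end>_<F|R>_<n_ins>_<n_del>_<n_sub>_<0|1>
e.g.  r7_c1_100_289_F_1_2_1_0
```

Underscores in contig names are escaped (`_` → `%u`, `%` → `%p`); the final
field flags random reads, which carry sentinel coordinates `*_0_0`. The
truth TSV is authoritative when both are present.

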