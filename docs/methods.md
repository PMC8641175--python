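# Methods

`deepdel` detects deletions (≥ 50 bp lost relative to the reference) from
long-read alignments. This note documents the model, its assumptions, the
tunable parameters, the synthetic benchmark, and the numerical choices made
where the design was genuinely open.

## Signal model

A deletion in the sequenced individual shows up in read alignments as `D`
(deletion) operations in CIGAR strings: reads spanning the missing sequence
align on both sides, and the aligner bridges the gap with a `D` op whose
length approximates the deleted span. Sequencing noise — especially in
noisy long reads — also produces spurious small indels, so single-read
evidence is unreliable; the signal is the *column* of consistent, long `D`
ops across the reads covering a locus.

The pipeline turns this into a sequence-labeling problem:

1. **Windows.** The reference is tiled into non-overlapping windows of
   `m = 200` bp (0-based, half-open coordinates everywhere internally).
2. **Feature matrices.** For each window, every read whose aligned
   reference span intersects it contributes a binary bitmap row of length
   `m`: position `j` is 1 iff a `D` op covers reference base
   `window.start + j`. Only `D` ops count; `N` (skip) ops consume reference
   but are not deletion evidence. Rows are sorted by deletion count
   descending (read name breaks ties, so output is deterministic),
   truncated to the top `n = 18` rows or zero-padded up to `n`. A read
   with no `D` op in the window still contributes an all-zero row that the
   truncation rule may displace. The number of overlapping reads `p` is
   recorded.
3. **Classification.** `T = 100` consecutive windows form one sample. Each
   window matrix is encoded independently by a shared convolutional
   encoder into an `F = 160`-dimensional vector; the sequence of 100
   vectors runs through two bidirectional LSTM layers (64 units per
   direction) and a two-layer fully connected head with dropout; a sigmoid
   emits one deletion probability per window. The recurrent core lets
   evidence from neighbouring windows (deletions frequently span several)
   sharpen each window's score.
4. **Calling.** Windows scoring strictly above 0.5 are merged into
   candidate regions when index-consecutive. Within a region, every `D` op
   longer than 20 bp in an overlapping read yields a `(location, size)`
   signature; signatures are clustered on location (|Δlocation| < 40 bp),
   the largest cluster wins, and the (half-up rounded) mean location and
   size become the call, reported as a symbolic `<DEL>` VCF record with
   `SUPPORT` = cluster size. A region with no qualifying signatures falls
   back to its own bounds, flagged `IMPRECISE`.

## Encoder architecture

The design fixes the skeleton — an initial 1×2 average pool, six blocks
of conv → ReLU → squeeze-and-excitation → max pool, and a 160-dimensional
output — while the per-block filter counts, kernel sizes, pool shapes, SE
reduction ratio and head widths are free choices. The defaults here were
chosen so the encoder emits exactly 160 features and the whole model
stays under 1 M parameters (it has ≈ 274 k):

| block | filters | kernel | pool |
|------:|--------:|-------:|-----:|
| 1 | 8  | 3×3 | 2×2 |
| 2 | 16 | 3×3 | 2×2 |
| 3 | 16 | 3×3 | 1×2 |
| 4 | 32 | 3×3 | 2×2 |
| 5 | 32 | 3×3 | 1×2 |
| 6 | 64 | 3×3 | 1×2 |

followed by global average pooling and a linear projection to 160. The SE
bottleneck reduction is 4; the head widths are (64, 32) with dropout 0.4
after each fully connected layer. All of these live in `ModelConfig` and
can be overridden. Matrices are fed to the encoder with rows = reads and
columns = window positions; pooling mostly collapses the position axis.
This orientation is a single constant (`MATRIX_ORIENTATION`) imported by
both extraction and the network so it cannot drift. No normalisation or
augmentation is applied to the binary matrices.

The network is implemented directly in NumPy — im2col convolutions, BPTT
through the LSTM layers, Adam — with every layer's backward pass verified
against central finite differences in float64. Production arithmetic is
float32. Max-pool gradient ties are resolved to the first element in scan
order; pooling crops rows/columns that do not fill a complete pool cell.

## Loss

Training minimises the class-asymmetric squared-log loss

    L(p, y; a) = (ln(p − y + 1 + a))²,  a = 0.001,

read as the square of the logarithm: for a missed true deletion
(y = 1, p → 0) the loss approaches (ln a)² ≈ 47.7, while a confident
unconfirmed prediction (y = 0, p → 1) costs only (ln(2 + a))² ≈ 0.48. The
alternative reading ln(x²) is negative for x < 1 and cannot produce this
asymmetry, so it is rejected. The asymmetry matches truth sets that are
precise but incomplete, and supplies large gradients for the rare positive
class (~1–3% of windows in the synthetic benchmark, ~1% in real call
sets). The argument is clamped to 10⁻¹² to stay finite under any numeric
violation of the contract. The per-sample loss is the mean over unmasked
windows.

## Training

Adam at learning rate 0.001; data shuffled every epoch from a recorded
seed; batch size counted in windows (default 512, rounded up to whole
T-window samples) so that positive windows are present at most steps
despite the imbalance. Early stopping monitors window-level AUC on the
validation genome (mean training loss when no two-class validation set
exists), keeps the best checkpoint, and stops after 10 epochs without
improvement. Weight initialisation is Glorot-uniform from a recorded seed;
the LSTM forget gates start at bias 1. Gradients are clipped to global
norm 5 as a stability guard. An
all-negative training set is refused with an explanatory error.

## Synthetic benchmark

The simulator emulates the data regime the method targets without any
downloads: a uniform-random reference, non-overlapping implanted deletions
(uniform sizes, default 50 bp–5 kb) separated by at least two window
lengths, and long reads (log-uniform 1–20 kb) sampled uniformly along the
donor (deletion-applied) genome at a target coverage. Reads are emitted
*pre-aligned*: each CIGAR is constructed exactly from the known
donor-to-reference mapping, so an implanted deletion inside a read appears
as a `D` op of the true size at the true location. This removes the
aligner dependency and makes downstream expectations exact; a FASTQ
export exists for real-aligner integration tests.

Noise is emulated by (a) spurious small deletions (default 1–30 bp at
5×10⁻⁴ per base): the read *loses* those bases while its reference span is
unchanged, exactly as a sequencing dropout appears in a real alignment, so
true deletion coordinates stay anchored; and (b) base mismatches (default
1%), which change `SEQ` but not the CIGAR (`M` covers both). Because noise
deletions can exceed the caller's 20 bp signature filter, they exercise
both the filter and the clustering. Deletions are homozygous by default;
heterozygous mode routes half the reads through the unmodified reference.

What the simulator does **not** emulate: platform-specific error profiles
(CLR vs CCS), insertions and other SV classes, alignment ambiguity in
repeats, mapping-quality variation, and reference bias. Passing the
synthetic benchmark therefore demonstrates that the pipeline's mechanics
are correct and that the architecture can learn the deletion signature —
not that the defaults reach published performance on real genomes, which
requires training on real alignments at scale.

The acceptance benchmark ("easy regime") uses three disjoint genomes —
train, validation, test, mirroring a chromosome-disjoint split — of 1 Mb
each with 20 implanted deletions of 50–2000 bp, 30× coverage, noise rate
5×10⁻⁴, all seeded from one root seed. These sizes keep the full loop
(simulation, extraction, ~35 training epochs, calling, scoring) around
five minutes on one CPU core while leaving ≈ 97–98% of windows negative.
The default `SimulationConfig` genome is 2 Mb for the same class-balance
reason.

## Numerical and design choices

- **Coordinates** are 0-based half-open internally; VCF output is 1-based
  with `POS = start + 1`, `END = POS + size`, `SVLEN = −size`. Calls are
  not genotyped (`./.`).
- **Alignment filters:** unmapped, secondary and QC-fail records are
  always skipped; supplementary alignments are kept (split reads carry
  deletion evidence); minimum mapping quality is configurable, default 0.
- **Clustering linkage:** the pairwise |Lᵢ − Lⱼ| < 40 rule is ambiguous
  for chains; the default is single-linkage chaining on sorted locations
  (deterministic and order-independent), with centroid linkage available
  behind a flag. On chains like 100/135/170 the two differ (documented in
  the tests); the acceptance suite only checks instances where the
  transitive closure is unambiguous.
- **One call per region:** the largest cluster is selected (ties go to
  the smaller mean location); multi-allelic regions are a known
  limitation. Means are rounded half-up.
- **Contig tails:** a final window shorter than `m` is zero-padded on the
  right; a final batch shorter than `T` is zero-padded with a validity
  mask, and masked windows are excluded from the loss and never reported.
- **Evaluation** uses greedy one-to-one matching by ascending breakpoint
  distance with defaults of 500 bp distance and 0.7 size similarity — a
  documented simplification of standard SV benchmarking tools, not a
  reimplementation of them. AUC is rank-based with midrank ties.
- **Truth loading** accepts VCF (symbolic `<DEL>`, `SVTYPE=DEL`, or
  REF/ALT length difference; size from `SVLEN`, else `END − POS`) and BED;
  records under 50 bp are dropped by default. Genotypes are ignored; any
  nonzero window overlap labels the window positive.

## Known limitations

- Deletions only; insertions, inversions and duplications are out of
  scope, as are pileup/base-quality features.
- Scores do not share context across batch boundaries (each T-window
  sample is scored independently).
- The greedy matcher and the simplified truth handling are not a
  substitute for publication-grade benchmarking with dedicated tools.
- CPU-bound NumPy training is practical at benchmark scale only; training
  on real whole-genome data would require a GPU framework implementation
  of the same architecture.
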