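# Methods

`idrpipe` is a desk-scale pipeline from amino-acid sequence to ensemble
properties for intrinsically disordered regions (IDRs): design synthetic
sequences, simulate them with a one-bead-per-residue model, measure the
ensemble, normalize against a Gaussian-chain null, scan proteomes with a
sliding window, quantify conservation of dimensions across homologs, and
train a fast recurrent surrogate on simulator output.

## Coarse-grained model

Each residue is one bead. The potential energy is

```
U = sum_bonds k (r - r0)^2
  + sum_{|i-j|>=2} U_WF(r; eps_ij, sigma_ij, mu, nu)
  + sum_{|i-j|>=2} U_DH(r; q_i, q_j)
```

* **Bonds** — harmonic, `k = 9.6 kcal/mol/A^2`, `r0 = 3.81 A` between
  consecutive beads. Nonbonded terms exclude 1–2 pairs only; 1–3 pairs
  interact (standard for bead–spring chains).
* **Wang–Frenkel pair potential** —
  `U_WF(r) = eps * alpha * [(sigma/r)^(2mu) - 1] * [(Rc/r)^(2mu) - 1]^(2nu)`
  with cutoff `Rc = 3 sigma`, where `alpha` is the closed-form
  normalization making the well depth exactly `-eps`. The potential and
  its derivative vanish identically at the cutoff, so no switching is
  needed. The builtin set uses `mu = 2`, `nu = 1` for every pair.
* **Debye–Hückel electrostatics** —
  `U_DH(r) = C q_i q_j exp(-r/lambda_D) / (eps_r r)`, energy-shifted to
  zero at a 35 A cutoff (about 4.5 Debye lengths, where the residual
  force discontinuity is negligible). `lambda_D` comes from the standard
  closed form; at 150 mM, 300 K, `eps_r = 80` it is 7.95 A.

### Builtin parameter set (synthetic)

The builtin `"mpipi"` parameter set is a **synthetic reconstruction** in
this functional form, not a published pair table: exact average residue
masses; scaled charges R/K = +0.75, D/E = −0.75, histidine neutral;
per-residue `sigma` from residue van der Waals diameters combined by the
Lorentz rule; and `eps_ij = 0.8 * (lambda_i + lambda_j)/2` kcal/mol from a
hand-defined stickiness scale `lambda` in which aromatics (W 0.95, Y 0.90,
F 0.85) dominate, aliphatics are intermediate and charged residues are
weakest. This reproduces the qualitative sequence–ensemble phenomenology
(aromatics compact, charge and proline expand) but is not quantitatively
calibrated against experiment. All physics code is parameter-set-agnostic:
any complete 20-bead/210-pair file in the documented text format can be
loaded, and `"mpipi-gg"` is a named slot for such a file.

## Simulation protocol

Single chains in a 500 A cubic periodic box (minimum image; at these
sizes a chain never sees its image — asserted at run time). Starting
structures are self-avoiding random coils (sequential placement at the
bond length, 3.8 A hard core, backtracking), then energy-minimized by
backtracking steepest descent (up to 1,000 iterations or a max per-bead
force below 1e-8 kcal/mol/A).

Dynamics are NVT Langevin with the BAOAB splitting at a 20 fs timestep,
300 K target, and friction `gamma = 1/(100 ps)` (the thermostat coupling
time). BAOAB reduces to velocity Verlet as `gamma -> 0`, which the test
suite uses to verify near-NVE energy conservation; canonical correctness
is verified against the closed-form bond-length distribution of a
harmonic dimer and against equipartition (kinetic temperature). Kinetic
temperatures are measured from on-step velocities and carry the usual
O((omega dt)^2) discretization bias, below 1% for these force constants.

Two presets:

| preset | production | equilibration | frame spacing |
|--------|-----------|----------------|----------------|
| `paper` | 6 us (L <= 250) / 10 us (L > 250) | 10 ns | 2 ns |
| `desk`  | 200 ns | 5 ns | 1 ns |

The `desk` preset is the package's own scaled-down protocol sized so a
50-residue chain completes in minutes on one CPU; all shipped tests and
the acceptance script use it. Equilibration frames are discarded. A
production length of exactly 250 residues is ambiguous under the
length rule and maps to 6 us with a warning. Replicate seeds derive
deterministically from the base seed; a fixed seed reproduces a
trajectory bitwise on one platform.

## Ensemble observables

From each frame: the mass-uniform gyration tensor (mass weighting
optional), `Rg = sqrt(trace)`, end-to-end distance `Re`, and asphericity

```
delta = 1 - 3 <lam1 lam2 + lam1 lam3 + lam2 lam3> / <(lam1+lam2+lam3)^2>
```

with the ensemble averages taken before the ratio (a per-frame-ratio
option exists; both are bounded in [0, 1]). The internal scaling profile
is the mean spatial distance at each sequence separation; the polymer
scaling law `R(delta) = R0 * delta^nu` is fitted by least squares in
log–log space on separations `delta >= 10`, excluding the bond-dominated
short-range regime (the default fit floor is a package choice).

The Gaussian-chain null model (analytical-Flory-random-coil style) uses
`Re_null = b_eff * sqrt(N)`, `Rg_null = Re_null / sqrt(6)` with
`b_eff = 3.81 A`, the bond length of the shipped parameter set, which is
the ideal-chain (nonbonded-off) limit of the simulator. Only the
exponent 0.50 is guaranteed; the absolute prefactor is calibration.
Normalized dimensions divide the measured `Rg`/`Re` by this null:
values above 1 are expanded, below 1 compact. Note that the Gaussian
identity `Re^2/Rg^2 = 6 N/(N+1)` holds for mean-square (RMS) dimensions;
the ratio of mean values is smaller (`<Re>^2 = 8/(3 pi) <Re^2>` for a
Gaussian chain), so tests assert the mean-square form.

Replicate summaries report the mean over replicates and the standard
error of the mean (sample s.d. / sqrt(k)); with a single replicate the
s.e.m. is reported as undefined rather than zero.

## Sequence features

FCR, NCPR, class fractions (aromatic F/W/Y, aliphatic, polar, proline,
glycine, positive R/K, negative D/E), mean hydropathy (Kyte–Doolittle
rescaled to [0, 1] by default, configurable — no particular scale is
canonical for disordered regions), SCD
(`(1/L) sum q_i q_j sqrt(j-i)`), SHD (`(1/L) sum (h_i+h_j)/(j-i)`), and
kappa. Histidine is treated as uncharged everywhere (its charge at
neutral pH is small in residue-level models) and tracked as its own
composition class.

**kappa.** delta averages, over sliding blobs of sizes 5 and 6, the
squared deviation of the blob charge asymmetry
`sigma = (f+ - f-)^2/(f+ + f-)` from the whole-sequence value;
`kappa = delta / delta_max`. Finding `delta_max` is the delicate part: no
single fixed arrangement maximizes delta for every composition (interior
charge blocks are covered by more blobs than end-placed blocks). The
implementation searches a deterministic family of contiguous-block
arrangements — negative block, positive block, neutrals split around and
between them at every split point (capped for long sequences, where pad
sizes beyond two blob widths are interchangeable) — and polishes the best
candidate with a deterministic pairwise-swap hill climb for sequences up
to 200 residues, caching the result per composition. This keeps kappa in
[0, 1] across extensive randomized shuffle tests; for much longer
sequences the block family alone is used and kappa could in principle
exceed 1 by a sliver in adversarial cases. kappa is undefined (reported
as missing, never a number) for chargeless sequences, sequences shorter
than the largest blob, and degenerate compositions (for example all
charges of one sign) where even the reference arrangement has zero blob
variance.

## Sequence design

`design_by_composition` apportions fractional targets exactly
(largest-remainder rounding) and fills the remainder from a neutral
disorder-promoting background (G, S, N, Q, T by default — neutral so that
background fill never perturbs charge targets; the full disorder-promoting
alphabet including charged residues is available by argument). Positions
are shuffled by a seeded generator; identical spec + seed gives the
identical sequence. Rather than running an external disorder predictor,
designs are restricted to this disorder-promoting alphabet; a
`disorder_filter` hook accepts any external predictor.

`design_by_kappa` starts from a composition design and runs a seeded
greedy position-swap search (2% uphill acceptance to escape plateaus,
up to 1e5 swaps) until the target kappa is reached within tolerance;
target 1.0 returns the segregated arrangement in closed form. Titration
series default to 100 sequences per feature value at length 100, the
study design this module emulates; each record carries its own seed and
provenance, and infeasible values are reported as failures without
aborting the series. Sticker–spacer constructs concatenate
`n_repeats` blocks of (GS)-dipeptide spacers (2–120 residues) and
polytyrosine stickers (0–8), default eight repeats.

## Proteome scanning

IDR annotations (1-based inclusive TSV against a protein FASTA) are
length-filtered to 35–3,000 residues. For every 51-residue window inside
an IDR the estimator's `Re` is divided by the window-matched Gaussian
null; the estimator is a plugin (`sequence -> Re in A`) so the simulator,
the trained surrogate, or a closed-form stub can back the same pipeline.
Compact/expanded subregions are the bottom/top 2.5% tails of the pooled
window population. The quantile convention is: with `n` windows and
`k = floor(n q)`, the lower threshold is the (k+1)-th ascending order
statistic and calls are strictly below it — exactly `k` calls when values
are distinct, zero when all values tie. Per-protein counts report both
raw windows and merged maximal runs of consecutive windows (the "ten or
more subregions" filter can be read either way, so both are emitted).
Amino-acid enrichment is the per-residue log2 ratio of tail to background
composition with a 0.5 pseudocount per residue class. The apparent
`Rg`-versus-length scaling exponent is a log–log least-squares fit with
per-record deviations (above = expanded, below = compact) returned as
diagnostics.

## Homolog conservation

A reference protein's folded/IDR segmentation (domains must tile the
ungapped reference) is mapped to alignment-column spans; insertion
columns between domains are absorbed into the adjacent disordered span
(IDRs grow, folded domains do not), and leading/trailing columns attach
to the terminal domains, so every member's segments concatenate to its
full ungapped sequence. Filters: the whole set is dropped if the
reference IDR is under 40 residues; members under 15 residues are
dropped; a set must retain the reference plus more than ten members
("more than ten" read strictly: at least 11). Dispersion uses sample
(n−1) standard deviations of member length and estimated `Re`, alongside
the Gaussian-null `Re` dispersion over the same lengths — equal length
spread with much lower `Re` spread than the null is the signature of
conformational buffering.

Similarity scores use BLOSUM62 (shipped as an NCBI-layout text fixture).
SumOfPairs sums the substitution score over all unordered row pairs per
column; StarScore scores the column consensus (most common residue, ties
broken alphabetically, gaps excluded) against every row. Gap–residue and
gap–gap pairs contribute 0 but columns still count toward the
normalization by (rows × columns).

## Surrogate regression

One-hot encoding over ACDEFGHIKLMNPQRSTVWY; a stacked bidirectional GRU
(1–2 layers, hidden dimension 10–55, defaults 2×32) with final-state
pooling of both directions into a linear scalar head; L1 objective;
Adam at learning rate 0.001 by default. The network and
backpropagation-through-time are implemented directly in numpy, which
keeps training deterministic per seed; gradients are verified against
central differences in the test suite. Variable-length batches are
padded and masked with the recurrent state frozen past each true length,
so batched predictions equal single-sequence predictions exactly.

Labels are standardized (z-scored on the training partition) before the
L1 objective and un-standardized at prediction — L1 steps are scale-
sensitive, and this keeps one learning rate usable across label kinds.
The data split is 64:16:20 train:validation:test with largest-remainder
rounding (exact counts), five-fold cross-validation over the train+val
pool, 500 epochs per fold and 750 for the final model; returned weights
are those of the epoch with the lowest validation loss (loss
monotonicity is not assumed — only the argmin selection contract).
Separate single-property models are trained per observable rather than
one multi-task network.

## What the synthetic data does and does not show

The generators produce disorder-promoting synthetic sequences, ideal and
repulsive reference chains, and closed-form labels. Tests on them verify
the machinery: exact geometry (asphericity limits, null-model exponent),
statistical mechanics (canonical dimer statistics, equipartition,
ideal-chain scaling), algorithmic contracts (quantile tail counts, split
arithmetic, gradient correctness) and directional sequence effects
(charge expands, tyrosine compacts). They do not validate the synthetic
parameter set against experimental ensembles, and surrogate recovery of
a closed-form composition label does not imply the accuracy of a
simulator-trained model on natural IDRs.

## Numerical choices and problem sizes

Desk-scale runs used by the tests and the acceptance script: a 200 ns /
30-residue thermostat check, a 200 ns / 100-residue ideal chain, an
80 ns / 60-residue repulsive-versus-ideal pair, a 200 ns dimer, ~12 ns
window-estimator runs, and a 500-sequence surrogate recovery at length
50 — sizes chosen so the whole suite runs on one CPU in well under half
an hour. Pair interactions use direct O(N^2) summation (exact; at these
chain lengths a neighbor list buys nothing). Integer Wang–Frenkel
exponents (2 mu, 2 nu) are required by the numba kernel so inner-loop
powers are repeated multiplications. The integrator aborts with a
timestep diagnostic if any bond exceeds 40 A. Minimization guarantees a
non-increasing energy sequence; overlaps below a 0.8 A hard floor raise
an error suggesting re-minimization.

## Known limitations

* The builtin parameter set is qualitative (synthetic); quantitative work
  requires a calibrated parameter file.
* Single chains only: no multi-chain condensates, no folded domains, no
  pH titration of histidine.
* kappa normalization is exact-by-search, not closed form; see above.
* The surrogate is CPU-bound numpy; it is meant for desk-scale corpora
  (hundreds to thousands of sequences), not the full training scale of a
  production predictor.
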