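# Methods

`trem2map` implements the computational side of a TREM2 ligand-engagement
analysis: a sequence-only screen for candidate binding regions between TREM2
and IL-34, a biolayer-interferometry (BLI) kinetics stack for K_D
determination across a receptor point-mutant panel, and quantification of
sequential competition experiments. Raw instrument data are emulated by a
fully seeded synthetic generator, so every result in the test suite is a
round trip through the same code a user would run on real exports.

## Hydropathy-complementarity screen

Each protein is reduced to its Kyte–Doolittle hydropathy profile H(i)
(range −4.5 for Arg to +4.5 for Ile; no residue scores exactly 0, so the
binary +/− hydrophobicity map is always defined). A motif of length L —
an IL-34 helix, a TREM2 CDR loop, or a basic-site strand — is slid over the
partner's full map at every offset (window step 1), in both forward and
reverse residue order; the reverse orientation models antiparallel backbone
pairing. Each alignment is scored with:

* **percent match** — percentage of aligned positions with opposite signs;
* **degree of complementary hydropathy** —
  `C = Σ |H(i) − H'(i)| / (9 L)`, in [0, 1]. The absolute value makes the
  stated 0–1 range hold; a signed sum could go negative. C = 0 iff the two
  index vectors are identical and C = 1 iff every aligned pair is the
  Ile/Arg extreme.

A hit is *good* when percent match > 75 and C > 0.5, both strict, with no
rounding before comparison. Good hits are clustered on the target by
interval union, bridging runs of unhit residues up to `gap_tolerance`
(default 3 — the smallest value that merges CDR2 (69–75) hits with hits on
the flanking basic strands (62–68, 76–78) into one region). Because the
gap rule is a modelling choice rather than a measured quantity, the
pipeline always emits a gap-sensitivity table of region counts over
gap_tolerance 0–8 alongside the default clustering.

Coordinates are 1-based inclusive on the full UniProt precursor (signal
peptide included) so mutations such as R47H or R76D keep their
conventional numbering; a BED-style 0-based half-open export exists behind
an explicit flag.

Segment definitions (packaged in `data/segments.cfg`): TREM2 Ig domain
18–130 as target; motifs CDR1 39–46, CDR2 69–75, CDR3 88–91 and basic
strands 47–50, 62–68, 76–78, 112–114. IL-34 target 21–242 (mature chain);
helix motifs 2–6 at 71–85, 90–100, 119–129, 142–151, 156–179. Helix 1 has
no annotation in the source material available to this package; 31–54 was
adopted from the canonical helix-A region of the IL-34 crystal structure
and is recorded here as a design choice. Region *counts* on the IL-34 side
are robust to this choice (Helix 1 contributes no good hits at default
thresholds); the TREM2-side clustering is sensitive to the exact helix
spans, and the screen reports one marginal single-hit cluster (23–33)
beyond the two major regions — users supplying a structure-derived helix
annotation should pass their own segments file.

The packaged TREM2 (Q9NZC2) and IL-34 (Q6ZMJ4) precursor sequences were
validated against 22 published residue anchors (every mutated panel
position plus the two IL-34 salt-bridge partners D107/E111) and the exact
precursor lengths (230/242 aa).

## Variant panel

Variant names (`W44D/L69D/L71D`) parse into position-sorted substitutions;
applying them to a sequence verifies the expected wild-type residue at
every position, which catches numbering-offset errors immediately.
Positions classify into binding surfaces — hydrophobic {41, 44, 69, 70,
71, 74, 89}, basic {46, 47, 62, 76, 77, 78}, basic-adjacent {75, 85},
site 2 {122, 123} — with AD-risk positions {47, 62, 87, 96} carried as a
flag (87 and 96, which sit in no structural surface, classify "AD-risk").
Sets spanning surfaces classify "mixed". The packaged K_D table keeps
qualitative entries ("N.B.D.", "No Binding", "Decreased binding",
"Binding (not fit)") as typed sentinels; arithmetic on them is refused,
never silently NaN. The panel fixture covers the 24 variants named in the
binding tables; the full 28-member library is not enumerated in the
available source material, and missing rows are omitted rather than
invented.

## BLI kinetics

The 1:1 Langmuir model is used in closed form: association
`R(t) = Req (1 − e^{−kobs t})` with `kobs = kon c + koff` and
`Req = Rmax c/(c + K_D)`; dissociation decays with `koff`. Double
referencing subtracts a loaded-sensor-in-buffer trace and a bare-sensor-
in-analyte trace, after aligning each trace by its baseline mean, so a
trace referenced against itself is exactly zero.

Two K_D routes:

* **Steady state** — Req is the mean of the final 10 % of the association
  phase (flagged when the trace is still rising by more than 1 % relative
  to the preceding window); Req(c) is fit to the one-site hyperbola by
  least squares (lmfit). Initialisation: K_D from the concentration
  nearest half-maximal response, Rmax = 1.2 × max response; positive
  bounds. A series with no curvature is reported non-converged.
* **Kinetic** — global least squares of shared (kon, koff) and a global
  Rmax over ≥3 concentrations, association and dissociation jointly. A
  two-component comparison fit sets `biphasic_flag` when it improves the
  residual RMS more than 2-fold, marking data (e.g. oligomeric analytes)
  for which a 1:1 K_D is not meaningful.

Since binding tables report only K_D, simulators accept any (kon, koff)
factorization at fixed K_D; the default is koff = 0.01 s⁻¹. Fold changes
versus wild type are reported as a factor ≥ 1 with a direction derived
from the K_D ratio alone (lower K_D = affinity increase); the source
tables' arrow glyphs are not reproduced because they are internally
inconsistent (compare the entries for D87N and R122D/K123D, both with K_D
below wild type).

## Competition

Sequential assays are simulated by integrating the competitive occupancy
ODE `dR_A/dt = kon_A c_A (Rmax − R_A − R_B) − koff_A R_A` (LSODA,
rtol 1e−9) across baseline / first association / dissociation / second
association, with well concentrations switching at phase boundaries: the
competitor is present only in the first association, so afterwards it can
only dissociate — the mechanism behind order-of-addition asymmetry. The
readout is the second-association *step height*, which insulates against
incomplete dissociation; percent decrease versus the matched
no-competitor control arm is clipped at 100 (a negative step means the
pre-bound competitor's run-off exceeds probe binding, i.e. complete
block). Classification cutoffs: full block ≥ 90 %, none < 10 %
(configurable).

Default competition parameters factor the competitor's K_D with
koff = 1e−4 s⁻¹ and use a 600 s first association. This is deliberate:
with the generic 0.01 s⁻¹ off-rate a pre-bound competitor loses ~95 % of
its occupancy during a 300 s second association and complete block cannot
occur at any concentration, whereas the avid oligomeric ligands used as
competitors in practice dissociate far more slowly. Under these settings
a shared-site titration (K_D 281 nM competitor vs 500 nM probe at
K_D 526 nM) is monotone and crosses 95 % block in the µM range, and
swapping the ligand order reverses the strength of inhibition — the
qualitative signatures the analysis is designed to detect.

## Synthetic data

Generators are pure functions of (parameters, seed); metadata embedded in
every trace suffices to regenerate it bit-exactly. Defaults mirror the
study conditions: concentration series 62.5–1000 nM (two-fold) for
C1q/IL-34-style runs and 0.0122–50 µM (two-fold, 13 points) for apoE4-style
titrations; additive Gaussian noise in response units; optional linear
drift. Planted-complementarity sequence pairs choose, per motif residue,
the opposite-sign residue with the largest index difference, guaranteeing
100 % sign match and per-pair |ΔH| ≥ 4.9 (C ≥ 0.544), so planted windows
are recovered by the screen with full sensitivity — a labelled benchmark
for the screening code. Background composition is uniform over the 20
residues.

What the generator does *not* emulate: mass-transport limitation,
bivalent/avidity kinetics, spike or step instrument artifacts, well
depletion, and non-specific binding. Passing round-trip tests therefore
demonstrates correctness of the fitting machinery under the stated model,
not robustness to every pathology of real sensorgrams.

## Problem sizes and numerics

Test simulations use 1–2 s sampling over 300–900 s phases and ≤ 60-seed
repeat studies, sizes chosen so the full suite runs in seconds while
leaving the fits statistically overdetermined. ODE tolerances (rtol 1e−9,
atol 1e−12) keep integrator error far below the 1 % comparisons made
against closed forms. Fit convergence is declared only when the optimizer
reports success *and* usable error bars; steady-state fits additionally
require the fitted K_D to lie within 100× the probed concentration range.

## Known limitations

* The clustering gap rule and the IL-34 helix annotation are design
  choices where the source material is silent; both are exposed as
  configuration and their sensitivity is reported rather than hidden.
* Competitive K_i estimation and ternary-complex models are out of scope;
  the competition module quantifies block, it does not fit it.
* The kinetic fitter assumes shared kon/koff across sensors and no
  mass-transport term; biphasic data are flagged, not modelled further.
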