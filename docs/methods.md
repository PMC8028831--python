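# Methods

## The model

`digevo` simulates populations of self-replicating computer programs
("organisms") on a periodic 2-D lattice.  An organism is a fixed-length
genome of 120 instruction-sites, each holding one of 32 instructions, run by
a small virtual CPU: three 32-bit registers (AX/BX/CX), two stacks, four
heads into a working tape (instruction pointer, read, write, flow), a
three-slot ring of recent environmental inputs, and the label most recently
copied.  The lowercase letters `a`–`z` carry the canonical heads instruction
set; `A`–`F` add the null instruction nop-X, directed and broadcast
messaging, message retrieval, and the two rotations.  The full
code-to-semantics table ships as `digevo/data/instructions.tsv` and is the
single source used by both the VM and this documentation.

Replication is explicit: `h-alloc` doubles the tape to 240 sites (offspring
scratch at 120–239, pre-filled with nop-X), `h-copy` moves one instruction
from the read head to the write head, and `h-divide` splits off the
offspring region, which is born into the cell the parent faces, replacing
any occupant.  Organisms die only by replacement.  Nop runs double as
templates: `h-search` finds the cyclic complement (A→B→C→A) of the template
following it and parks the flow head just past the match; `if-label`
executes its guarded instruction only when the most recently copied nops
equal the complement of its template — the ancestral mechanism for dividing
exactly when copying is complete.

### Divide condition

`h-divide` fires only once at least `min_copy_fraction` (default 1.0) of
the 120 offspring sites have been written.  This choice is what makes
validation-free replicators expressible at fixed genome length: a loop that
attempts `h-divide` every iteration simply wastes one cycle per iteration
until copying completes, whereas an `if-label`-guarded loop skips the
attempt.  The efficiency difference, not offspring viability, is then what
distinguishes guarded from unguarded loops.  The real platform's channel of
partially copied, largely non-viable offspring arises from variable-length
division and cannot be reproduced faithfully at fixed length; lowering
`min_copy_fraction` re-opens that channel for experiments, at the price of
making front-half-only replicators the stable form.

### Tasks, resources and merit

The environment supplies uniform random 5-bit inputs each time an organism
executes `IO`.  The nine logic tasks (NOT, NAND, AND, ORN, OR, ANDN, NOR,
XOR, EQU; merit values 1, 1, 2, 2, 4, 4, 8, 8, 16) are checked on every
output: a task is performed when the output equals the task's function
applied to one (NOT) or an ordered pair of the up-to-three buffered inputs,
in 5-bit arithmetic.  Each task has its own resource, kept near a
steady-state level R\* per lattice site by a chemostat (per-update
relaxation δ, default 0.01) with lateral diffusion toward the 8-neighbour
mean (default coefficient 0.5 — fast enough that local depletion does not
persist).  A performance consumes `min(f·level, c_max)` of the local
resource (defaults f = 0.0025, c_max = 1) and accumulates
`value × consumed` into a bonus; at the next divide the organism's merit
becomes `120 × (1 + bonus)` and the offspring inherits it.  The linear
form, the uptake constants and the at-divide application are package
choices (the platform literature states proportionality but no functional
form); they keep rewards bounded while preserving the relative task
weights.

With 5-bit substrates, echoes and constants occasionally coincide with task
results, so random outputs can score; this background is part of the model
here (tasks may be rewarded repeatedly, resource-limited) and is shared by
all genotypes in any comparison.

### Scheduling

Each update, organism *i* receives `30 × min(merit_i/120, cap)` CPU cycles
(cap default 8), with largest-remainder rounding making totals exact; an
equal-merit population at basal merit executes exactly 30 cycles per
organism per update.  Merit is deliberately *absolute* rather than
zero-sum-relative: under a strictly proportional share a monoclonal world
executes 30 cycles/organism regardless of merit, and the clonal fitness
assay (below) would be blind to metabolic or signaling benefits — the
opposite of what that assay is for.  Messages are delivered at send time
(queue capacity 32, oldest dropped): an end-of-update delivery phase would
add at least two update-boundary latencies to a request/response exchange,
which exceeds the remaining gestation precisely for merit-boosted
organisms.

All randomness in a run flows through one seeded generator in a fixed
row-major draw order, so runs are bit-reproducible from (config, seed).
Mutation is substitution-only (length conserved forever) and applied once,
as a whole-genome per-site pass at divide: each site is redrawn uniformly
over all 32 codes with probability 7.5×10⁻⁴ (low) or 7.5×10⁻³ (high); the
configured rate is the event rate, self-substitution included.

## Assays

* **Isolation assay** — one organism, saturating resources, no neighbours:
  merit at first divide, gestation (cycles to first divide; ∞ for
  non-replicators), and the platform-internal fitness merit/gestation.
* **Population fitness assay** — 200 copies of one genotype on a dedicated
  225-cell world, mutation forced to zero, seeded-uniform placement and
  facings; fitness is the mean births/update over updates 101–500.  This
  captures same-genotype signaling benefits by construction.
* **Viability** — fraction of a genome set achieving at least one divide in
  isolation at R\* = 10,000 within 10× the ancestral gestation (4,680
  cycles).
* **Phenotype profile** — tasks performed over a single gestation with a
  scripted input cycle (3, 5, 9), chosen so that constant-zero outputs and
  input echoes never score a task by accident, making profiles exactly
  reproducible.  A joint profile runs two organisms in alternating
  30-cycle slices with mutual message delivery.
* **Marginal utility** of a process = (F − F_knockout)/F, where the
  knockout replaces every instruction of the process (e.g. messaging =
  send-msg, retrieve-msg, bcast1) with nop-X and both fitness measurements
  share one seed and configuration.  Zero by definition when the process is
  absent; undefined when F = 0.
* **Task complexity** — minimum number of two-input NAND gates composing a
  task, found by exhaustive breadth-first search over gate-reuse circuits:
  NOT 1, NAND 1, AND 2, ORN 2, OR 3, ANDN 3, NOR 4, XOR 4, EQU 5.

## Population statistics

Fitness distributions use a Gaussian KDE with Silverman's bandwidth on a
512-point grid spanning the data ±3 bandwidths; strict interior maxima are
peaks and each peak's genotype sample is exactly the values within ±2
bandwidths.  Genotypic heterogeneity is Σᵢ sᵢ over the 120 sites with
sᵢ = −Σⱼ pⱼⁱ ln pⱼⁱ (nats; 0·ln 0 = 0); phenotypic heterogeneity is the
Shannon entropy over the 512 phenotype classes.  Unimodality is tested with
Hartigan's dip statistic, implemented as the smallest sup-norm distance
between the empirical CDF and a convex-then-concave (unimodal) CDF fitted
through the ECDF band; ties are handled through interval constraints with
bisection.  The implementation reproduces the exact small-sample anchors
(1/(2n) for evenly spaced data, 1/4 for two equal point masses), and
p-values come from a seeded uniform-null bootstrap using the same
statistic.  Signaling-positive populations are those whose median messaging
utility exceeds the midpoint of the zero-centred and positive-shifted peaks
of the pooled utility KDE (fixed fallback threshold 0.05 when fewer than
two pooled peaks exist).

## Constructed genomes

The ancestor is a 120-site genome with the canonical head block (h-alloc;
h-search; mov-head placing the write head at site 120), a minimal metabolic
block performing NOT once per gestation, exactly one rotation instruction,
nop-C filler, and the terminal guarded copy-loop `z v f c a x g a b` with
end label `a b`.  Its gestation is exactly 468 cycles (9 head/metabolic
executions + 98 filler + 1 loop entry + 120 iterations × 3).  Archetype
fixtures modify the loop: two or four h-copies per iteration, with or
without the if-label guard (gestations 347/349 and 287 cycles).  The
messenger archetype is role-symmetric: it broadcasts its own input pair,
answers one retrieved request with a four-NAND NOR computation, zeroes its
registers, and late in gestation outputs retrieved values behind if-n-equ
guards so that, with messaging knocked out, the phase emits nothing.  In a
clone world the guarded outputs deliver NOR of the organism's own inputs
whenever a neighbour answered its broadcast; measured messaging utility is
≈ 0.69 and stable across seeds, and the knockout's utility is 0.

## What the synthetic conditions do and do not show

The desk-scale preset (world sizes 50/200, resources 0.1/100/10,000, 10
replicates, reduced update counts: 5,000 for conservation checks, 1,000 for
the evolution smoke test) regenerates the qualitative phenomena — rapid
fitness gain over the ancestor at the high mutation rate, nonzero
genotypic heterogeneity, messaging-dependent fitness in the constructed
archetype — but not the full study's peak landscape, which emerges from
100 replicates × 100,000 updates on the complete instruction-set
implementation.  Evolved-genotype structure here is therefore represented
by constructed archetypes, and the fitness-peak and incidence machinery is
validated on constructed mixtures rather than on full-scale evolved
ensembles.  Other known limitations: no variable genome length (hence no
true partial-birth channel), no death by starvation or age (so extinction
cannot occur and extinction deficits are structurally zero), no parasites,
demes or sexual recombination, and messaging carries plain register pairs
with no dedicated metabolic channel.
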