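# Methods

## The M-system formalism

An M system is a discrete-time model in continuous 3-D Euclidean space.
It contains three kinds of objects:

* **floating objects** — shapeless particles with a position, moved by
  Brownian motion each iteration (here: a nutrient `a` supplied by the
  environment and a division signal `s` produced inside cells);
* **tiles** — rigid 1-D rods or 2-D polygons that bond to one another
  through *connectors* (glued boundary sites; two connectors bond iff
  their glue labels match under a symmetric glue relation), so that
  larger structures self-assemble; tiles exist only where a creation
  rule has placed them;
* **protions** — protein-like channel/catalyst sites fixed on tiles;
  here a single type, `pore`, transports nutrients across a wall tile
  into the cell interior.

Interactions are reaction rules `u -> v` on multisets of objects, of
exactly four kinds: **metabolic** (transport across a tile through a
protion channel), **creation** (floating objects near a matching free
connector are consumed and a tile appears there), **destruction** (a
tile is annihilated), and **division** (a completed septum severs a
compartment in two). A rule instance is applicable when all of its
reactants lie within the *interaction radius* `r` of the reaction site
and on the prescribed side (inside/outside) of the membrane. One
iteration corresponds to one simulated minute.

Each engine step performs, in order: nutrient supply, a Brownian
displacement of every floating object (norm = mobility x `r`, direction
uniform on the sphere, reflected at the environment box), and the
application of a maximal conflict-free subset of applicable rule
instances in an order randomized by the run's generator; every object
is consumed by at most one instance, and each channel transports at
most once per iteration. All randomness flows from a single seed;
trajectories and censuses are bit-reproducible.

Assembly geometry (where a new tile's pose is, what a compartment is,
when a septum is complete) is delegated to an *assembly model* behind
the engine. The package ships two: a static bench-top assembly used by
the unit tests, and the bacterial chain assembly described next.

## The bacterial model

The bacterial cell wall is a closed octagonal prism: two octagonal
*pole discs* (edge length 1, the length unit of the model) cap a stack
of rings of eight rectangular *wall plates* (1 x 1), one pore protion
per plate. Cross-section containment uses the octagon's apothem
(~1.207). The inventory is exactly: four 2-D tile types (seed pole,
pole, wall plate, septum slice), three auxiliary rod types (seed, arc,
bridge), two floating objects, one protion type, and nine rules — one
metabolic (`a(out) -> a(in) + s(in)`: each imported nutrient releases
one unit of division signal inside), six creation (wall plate, pole,
septum slice, and the three rod types), one destruction (the rod
family), one division.

The life cycle, none of it scheduled explicitly:

1. the single seeded pole tile accretes a ring of eight wall plates
   from ambient nutrients, and a second pole closes the far rim: the
   first closed compartment;
2. the cell elongates by *inserting* a second ring of wall plates next
   to its newest pole, rigidly displacing the distal part of the
   assembly along the axis (wall insertion is how rod-shaped bacteria
   actually grow; a closed compartment cannot elongate by terminal
   attachment alone). Insertion slots consume internal nutrients, so
   elongation speed follows transport;
3. once both rings are complete, rod tiles consuming the `s` signal
   assemble a ring at the mid-cell seam (one seed rod, six arc rods,
   one closing bridge rod) and template eight triangular septum slices
   that close the mid-plane;
4. when the septum disc is complete, the division rule splits the
   compartment: cell count rises by one, every tile is retained, and
   the single septum becomes the shared new pole of both daughters
   (septa become poles in real bacteria too). Daughters stay bonded in
   a chain — the model's simplification of cell separation — and each
   restarts the cycle at its septum side. The spent rods are then
   annihilated by the destruction rule.

Division timing is emergent: it requires enough imported nutrient to
build 16 wall/slice tiles and enough accumulated signal for 8 rods, so
maturity arises from transport kinetics, not from a preset iteration.
An adult cell one step before its first division comprises exactly 34
injurable components: 2 poles + 16 wall plates + 8 septum slices + 8
rods (a protion is counted with its host plate; removing the plate
deletes the protion with it).

Bonds are derived from contact: laterally adjacent tiles within a ring
or disc bond, and each of the eight positional columns bonds
consecutive tiles along the axis (a pole spans all columns; a rod or
slice intercalates at its seam, severing the direct wall-wall contact).
A complete septum's bonds are therefore exactly the cut separating the
two daughter walls, which is the division trigger's structural
precondition. Tiles left with no bonds — or whole fragments detached
from the main assembly — drift off and are lost.

### Environment and nutrient supply

The environment is an axis-aligned box (9 x 9 x 190 length units for
population runs — tall enough for the full chain; 9 x 9 x 20 for
single-cell injury runs). Nutrient policy:

* **limited protocol** (population growth): a one-shot stock of `a`
  objects (the nutrient budget) is placed uniformly in the box; a small
  bolus (40 objects, drawn from the same budget) surrounds the seeded
  tile, representing the rich medium it is placed into. As the culture
  consumes the stock the ambient density falls and growth stops with no
  external intervention — the census is sigmoidal by construction of
  the physics, not by a stopping rule.
* **unlimited protocol** (injury experiments): the box is held at the
  reference ambient density (0.1104 objects per unit volume) by
  injection every iteration, with no budget.

Environment floats are additionally *mixed*: each iteration a fraction
(`mix_rate`) is carried to a new uniform position, the well-mixed
(agitated-culture) reservoir approximation. Without it, uptake around
the chain is diffusion-limited by a depletion shell and the bulk of a
tall box is unreachable within a run. Interior objects are never mixed.

Transport through a pore fires when an ambient `a` lies within `r` of
the channel; each import releases the nutrient plus one `s` inside the
compartment. Two regulatory features:

* **import saturation**: channels idle while the compartment already
  holds 5 nutrient objects (transport runs down the gradient only;
  prevents unbounded intracellular stockpiling);
* **membrane integrity**: a breached compartment's import capacity is
  scaled by (1 - f)^2.8, where f is the fraction of its built wall that
  is missing — channels fail individually and collectively as the
  gradient collapses. Breaches also exchange objects with the
  environment (escape 0.50 x f, admission 0.02 x f per object per
  iteration). All three matter only when f > 0, i.e. they leave
  uninjured growth untouched.

### Species presets

The three species differ only in calibration constants (the rule
inventory is identical): diffusion multipliers of `a`/`s`, the
agitation rate, and the nutrient stock. The shipped values — produced
with `scripts/calibrate.py`, which bisects the stock after the kinetic
constants set the sigmoid's time scale — are

| species | diffusion a/s | mix | stock | horizon (iters) | mean final cells |
|---|---|---|---|---|---|
| ecoli | 2.4 / 2.0 | 0.45 | 2250 | 100 | ~75 |
| slactis | 1.1 / 1.1 | 0.20 | 1780 | 150 | ~75 |
| lacidophilus | 0.5 / 0.7 | 0.045 | 1980 | 400 | ~85 |

all at interaction radius 1.1. With B_0 = 1 these populations
correspond to doubling times t log2 / log(B_n) of about 16, 24 and 62
minutes.

## Injury and self-healing experiments

Four injury kinds exist: deleting a tile (with consequent deletion of
its protions), deleting a protion alone, breaking a bond without
destroying the tiles, and injecting floating objects inside a membrane.
Glue bonding is spontaneous, so a broken bond between tiles still in
contact re-forms the next iteration; its lasting effect is through
detachment (a tile stripped of all bonds is lost). There is no repair
machinery: recovery uses only the nine growth rules, re-assembling
missing parts the way they were first built — but only where an
existing tile offers a connector to glue to (a fully destroyed region
cannot regrow).

Protocols (single cell, unlimited nutrients, 100 replicates per point):

* **sequential**: injuries drawn kind-uniformly at random times during
  growth, prior to septum division;
* **simultaneous**: the cell is grown to adulthood (septum complete,
  one step before division) and k distinct components of its 34 are
  deleted at once. This is the protocol behind the survival-threshold
  sweep; the kind-uniform sampler is also available
  (`sampling="kinds"`).

Survival means a completed division within 3x the uninjured mean
generation time (measured over 20 uninjured replicates); the cutoff
factor is the package's own convention. The recovery ratio is
the surviving runs' division time over that baseline; it is undefined
(None, never a number) when no run survives.

Under the shipped constants the survival probability is 1.0 through
~20 injuries, crosses 0.5 at 23-24, falls to a few percent at 26-28 and
to zero at 30+; the mean recovery ratio grows from 1.0 (uninjured)
to >2 near the lethal threshold. The threshold's location is set by the
membrane-integrity exponent: repair speed degrades as (surviving
channels) x (integrity)^2.8, both factors falling with the injury
count.

## Configuration-space framework

The configuration space M* of a system is the digraph of all distinct
configurations (equivalent ones merged) with one-rule transitions,
including nodes unreachable from the root that transition back into the
reachable part. The *h-components* are defined inductively: the forward
closure of every directed cycle seeds a component, every leaf seeds a
component, overlapping seeds merge, and a node whose forward closure
meets exactly one component joins it; the rest is the *morphogenetic
phase*. Production code computes this in closed form on the SCC
condensation (seeds are the closures of non-trivial SCCs plus leaves;
a node joins the unique seed group its closure reaches, if unique); the
test suite checks it against a brute-force oracle that literally
iterates the three clauses to a fixpoint. In a finite digraph every
maximal walk ends in a cycle or a leaf, so no node is left with a
seedless closure — asserted in tests rather than assumed.

An injury is an ordered pair (x, y) not producible by one rule; its
degree is the undirected distance in M*; it is sustainable iff x and y
share an h-component. The random-injury model draws x uniformly from
the homeostatic phase and y uniformly from the homeostatic nodes within
degree m of x (all of them, connected or not, when m is unbounded;
y = x, trivially sustainable, included). This convention makes two
equal disconnected components sit exactly at the 0.5 boundary (flagged
as a tie) and gives sustain probability 1/3 for three equal components.
A system is self-healing of degree m when the sustain probability at
degree m is at least 0.5. A dominating h-component holding at least
71% of all nodes guarantees self-healing of any degree, since both
endpoints land in it with probability > 0.71^2 > 0.5; 71 is the
smallest integer percentage with that property, and the implication is
verified exactly on randomly generated digraphs.

Exhaustive enumeration of configuration spaces is only attempted for
discrete toy systems (the n-slot chain with an optional reversible
attach/detach rule); the bacterial model's continuous space is explored
by sampling through the injury experiments instead.

## Growth kinetics

With one iteration = one minute and B_0 = 1, the doubling time is
G = t log2 / (log B_n - log B_0) and the growth rate K = log2(B_n)/t,
so G x K = 1 exactly. Reported values follow the two-decimal convention
of the reference table; for the slowest species the formula gives
400/log2(85) = 62.41 min. Sigmoidal profiles are fitted by least
squares on log-counts with the Zwietering reparameterisations of the
Gompertz and logistic models (asymptote A, maximum specific rate mu,
lag lambda), initialised from the plateau, the steepest rise and the
10%-span crossing; non-convergence and flat censuses are flagged on the
result, never silent. Fits run on the mean census across replicates.

## Numerical choices and limitations

* Obstruction tests use a 0.01 tile-edge clearance; minimum distances
  between placed shapes are computed by fan triangulation with exact
  segment/triangle primitives. The chain assembly places tiles on a
  deterministic template whose poses cannot collide, so it skips
  pairwise obstruction tests.
* Compartment membership is analytic (axial interval x octagon) in the
  chain assembly; the generic ray-casting point-in-polyhedron test is
  available for irregular assemblies.
* Conflict resolution is a uniform random permutation with
  first-come-first-served consumption; ties anywhere else break
  deterministically (position order), keeping runs bit-stable.
* The synthetic environment emulates a well-mixed batch culture with a
  single carbon-like resource. It does not model cell separation
  (daughters stay chained), wall thickness, hydrodynamics, tile
  flexing, realistic membrane chemistry, or DNA replication; passing
  tests support the self-assembly logic and the calibrated
  macro-observables, not microscopic realism.
* Population runs capture the census at the reference horizon; at 100
  iterations the E. coli curve is in its late deceleration phase, and
  the sigmoid's plateau is demonstrated explicitly on a smaller stock
  in the test suite (and visible at longer horizons).
* Mean-population calibration is accurate to a few percent; the
  survival 0.5-crossing fluctuates between 23 and 24 across seed sets,
  with a few-percent survivor fraction occasionally persisting at
  26-28 injuries.
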