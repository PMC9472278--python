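# Methods

## The reversible junction tree

A molecule is coarse-grained into a tree whose nodes are chemically valid
fragments: the SSSR rings, every bond outside a ring, and — where three or
more otherwise-unlinked fragments meet at one atom — a single-atom
"singleton" node that keeps the tree acyclic.  A plain junction tree of this
kind is not invertible: when two fragments share an atom, the tree does not
say *which* atom.  The representation here therefore stores per-edge **site
information**: the index of the shared atom in each fragment's canonical
atom order, and, for fused ring pairs (two adjacent shared atoms), a
direction ID saying whether the second shared atom follows (+1) or precedes
(-1) the first along the ring walk.  Spiro pairs are encoded as a type-2
edge with direction 0.  With this record, depth-first assembly of the
fragments is deterministic and `assemble(decompose(m))` reproduces `m`'s
canonical SMILES exactly — the property the whole package is built around,
and the reason every intermediate state of a design episode is a valid
molecule.

Index conventions that the source material leaves open were fixed as
follows:

* **Atom order** of a fragment is RDKit's canonical atom ranking of the
  fragment's standalone canonical form.  The same word therefore always
  exposes the same index frame, across runs and machines.
* **Ring walk** for direction IDs: canonical ranks are not a cyclic walk,
  so the walk is defined as the bond-path started at the rank-0 atom toward
  its lower-ranked ring neighbour.
* **Fragment symmetry**: symmetric fragments (benzene, the C-C bond) have
  automorphisms, so the rank frame of a particular occurrence is one
  automorphic choice.  All edges of a node are recorded in one frame, so
  any choice yields an isomorphic assembly; two different SMILES writings
  of the same molecule may produce different (equally valid) site records.
* **Aromaticity**: decomposition kekulizes first and extracts fragments
  with explicit bond orders; each fragment is then sanitized standalone, so
  an aromatic ring's word is its aromatic canonical form while a ring that
  is only aromatic in context (e.g. one ring of a fused pair) becomes its
  kekulé form.  Assembly merges fragments and lets RDKit re-perceive
  aromaticity; kekulization is deferred until after that re-perception, as
  merged flag states are not directly kekulizable.
* **Hydrogens** are implicit.  Explicit hydrogen counts on bracket atoms
  (e.g. pyrrole's `[nH]`, charged nitrogens) are decremented as assembly
  consumes their valence with new bonds.
* **Stereochemistry is dropped** on decomposition; extending site
  information with chirality flags is out of scope.

Scope limits: rings of more than eight atoms, ring pairs sharing more than
two atoms (bridged bicyclics), and polycyclic systems whose fragment
adjacency graph is cyclic (peri-fused aromatics such as pyrene) are
rejected as unsupported, both by the codec and by the dataset filter.

## The vocabulary and the site-code space

Fragment words are collected over the decompositions of a dataset and
sorted by canonical structure, so vocabulary construction is
order-independent.  Site records are flattened into one dense categorical
space of `8 x 8 x 6 = 384` codes: parent atom index and child atom index up
to the 8-atom ring maximum, and six direction codes (`NA` for type-1 edges,
four fused sign pairs, spiro `(0,0)`).  A fixed-width space keeps the policy
head static; codes that are structurally impossible for a given fragment
pair (indices beyond the fragment size, ring-only direction codes on
non-ring pairs) are masked to exactly zero probability at sampling time.
Chemically invalid but structurally well-formed attachments are *not*
masked: they are left to the environment's valence check and penalty, which
is what the training signal is meant to learn from.

## The tree-GRU encoder

Words and site codes are embedded with learnable matrices (`n_voc x d` and
`384 x d`).  Messages flow along every directed tree edge in two phases —
leaves to root, then root to leaves — through a GRU cell in the
junction-tree lineage: per-message reset gates, an update gate over the
summed incoming messages, and the edge feature concatenated onto the node
feature at every gate input.  The reversed direction of an edge uses the
site record with parent/child fields swapped, keeping messages directionally
informative.  A node's hidden vector is
`ReLU(W_out @ concat(x_i, sum_k m_ki))`; incoming messages are summed in
ascending neighbour order for bitwise reproducibility.  The aggregation
uses messages only (the edge feature enters through them), and the
two-phase schedule is rooted at the tree's stored root.

The network is implemented on a small tape-based reverse-mode autodiff
engine over NumPy float64 arrays (`rjtrl.nn.autodiff`), verified against
numerical differentiation.  Masked categories use a finite logit of -1e9 so
their probabilities underflow to exactly zero without producing NaNs in
entropy terms.

## Policy, value, and actions

An action has four components: stop, node, word, site.  The policy
factorizes autoregressively with the stop head first,

    pi = pi(stop | pool) * pi(node | {h}) * pi(word | h_node)
       * pi(site | h_node, E_node[word]),

where `pool` is the *sum* of hidden vectors (sum rather than mean pooling
lets tree size inform termination), the node head scores each node with a
shared two-layer MLP, and the site head is conditioned on the chosen node's
hidden vector and the chosen word's embedding.  The value head reads the
same pooled state from the same encoder evaluation.  On a stop action the
other components are unused; an action's log-probability is the sum of its
used heads, and its entropy the sum of their entropies.

## Environment and rewards

States are trees; the initial state is ethane (`CC`), the smallest
vocabulary word, unless a task specifies another seed structure.  A valid
attachment produces the reassembled, valence-validated molecule; an invalid
one leaves the state unchanged, emits `c_invalid` (default -0.5, the value
is configurable as only its sign and smallness are prescribed) and lets the
episode continue until `t_max` (default 30).  Two reward schemes exist:

* **step**: `r_t = R_step(t) - R_step(t-1)` with `R_step(-1) = 0`, so a
  clean episode's undiscounted return telescopes to the final molecule's
  score.  This difference form is adopted because it is the unique simple
  reading that makes the boundary definition `R_step(-1) = 0` necessary.
* **final**: zero reward until termination, then the final score.

The **duplication penalty** counts, over the whole training run, how often
each canonical product has been generated; once a molecule has been
produced more than `N_lim = 2` times, the terminal reward is chosen so the
episode's undiscounted return is exactly zero (in step mode, the negated
sum of already-emitted rewards).  Episodes that end with an invalid final
action are scored on the last valid molecule.

## PPO with expert learning

Training alternates rollout collection and minibatch updates of the clipped
surrogate loss plus `c_vf` times the value squared error minus `c_ent`
times the summed head entropy, with truncated generalized advantage
estimation (bootstrap value 0 at the terminal state) and per-batch
advantage normalization (flag-controlled, default on).  Full-scale defaults
follow standard PPO practice: clip 0.2, lambda 0.95, gamma 0.99, c_vf 0.5,
c_ent 0.01, Adam 3e-4, 64 episodes per update.

Expert learning extracts (state, action) pairs from a molecule's tree:
re-root at a random node, traverse breadth-first (depth-first selectable)
with children in random order, and pair each traversal prefix with the
attachment extending it, plus one stop example per molecule (weighted 1:1
with attach examples).  The policy's mean negative log-likelihood on these
examples is minimized standalone (pretraining) or jointly with the PPO loss
weighted by `c_exp`.

## Desk-scale study conditions

The canned runs in `rjtrl.runs` fix the scaled-down conditions used by the
test suite and the acceptance script: the built-in mini-vocabulary (20
words: nine common rings, nine common bonds, the carbon singleton and the
kekulé fused-ring word), hidden width 64, expert pretraining for 150 Adam
steps (3e-3) on 50 generated fixture molecules, and PPO with 8 episodes per
update, 4 epochs, minibatch 32, lr 2e-3 and c_ent 0.05 — more frequent
updates and a stronger entropy bonus than the full-scale defaults, chosen
because small-vocabulary problems explore a far smaller action space.  The
rediscovery task targets 2-(pyridin-4-yl)ethanol (`OCCc1ccncc1`), a 4-node
query (ring + two C-C bonds + C-O bond) built from ethane with step rewards
and the duplication penalty; episodes cap at 6 steps there and at 8 for
penalized-LogP maximization.

RL outcomes at this scale are seed-sensitive: at the fixed seed 0 the
rediscovery run reaches similarity 1.0 within a few hundred episodes, but a
majority of probed seeds plateau at the penultimate structure (similarity
0.75) within the 2000-episode budget — the fingerprint landscape's final
step requires one specific low-probability attachment.  The fixed-seed
protocol is therefore part of the stated conditions; the acceptance script
seeds all stochastic measurements from its `--seed` argument and reports
whatever the run achieves.  A behaviour-policy exploration mixture
(`PPOConfig.explore_eps`, default off) is available but did not improve
this task in probing: rare uniform draws are rate-limited by ratio clipping
and dilute the policy's own duplication-driven exploration.

## What the synthetic fixtures do and do not show

Fixture molecules are random vocabulary trees grown by rejection sampling
(structurally admissible site codes, valence-validated assemblies, products
re-checked to decompose under the same vocabulary).  They emulate small
drug-like molecules that respect the vocabulary constraints; they do not
reproduce the property distributions, functional-group frequencies or size
spectrum of a curated screening library, so passing tests demonstrate
correctness of the representation and training machinery, not
distribution-level fidelity to any real compound collection.  Full-scale
results additionally require pretraining on a large filtered library and
ten-thousand-episode runs, which are outside the desk-scale suite.

## Scoring functions

* **Penalized LogP**: Crippen LogP minus synthetic-accessibility score
  minus a large-ring penalty (`max(0, largest ring - 6)`), each term
  standardized with the benchmark-lineage ZINC250k constants (held in
  `PenalizedLogPConfig`, not hard-coded).  SA comes from RDKit's
  contributed scorer.
* **Similarity**: Jaccard/Tanimoto index of feature-typed circular
  fingerprints of radius 2 (FCFP4), via RDKit's Morgan generator with
  feature invariants.  Alcohol and ether oxygens hash to different bits, a
  deliberate example of the non-smooth landscape step rewards must cross.
* **Interaction score**: for each specified protein atom, the closest
  compound hydrogen-bond acceptor at distance d scores 1 below d_min =
  3.0 A, 0 above d_max = 6.0 A, linear between (the minimal monotone form
  consistent with the printed window); the total is the mean over protein
  atoms, and each protein atom pairs with its closest acceptor.  Both
  choices are isolated behind one function for easy replacement.
* **Multiobjective**: `c_intr * interaction - clip(dG, 500) - c_SA *
  max(0, SA - 4) - c_LogP * (max(0, -LogP) + max(0, LogP - 5))` with
  defaults c_intr 10, c_SA 1, c_LogP 5.  One-sided hinges at the printed
  thresholds are the minimal forms restricting the stated ranges.  Docking
  scores enter negated (more negative binding energy is better).
* **Docking** is an adapter contract only; the shipped engine is a
  deterministic mock (dG = -heavy atoms / 5, flat 2D pose, RDKit acceptor
  annotations) so end-to-end structure-based runs are testable without an
  external executable.

## Known limitations

* Bridged and peri-fused ring systems are unsupported by design; the
  dataset filter removes them.
* The NumPy autodiff engine is single-threaded and unbatched; full-scale
  (10^4-episode, 10^2-word) training is possible but slow compared to a
  GPU deep-learning stack.
* Canonical-rank frames make site records stable per canonical SMILES, but
  automorphic fragments admit several equivalent encodings; consumers must
  not compare site records across differently-written inputs.
* Node deletion and mutation actions are not implemented; generation is
  purely additive.
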