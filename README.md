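# bnrevert

Reverse control and reversibility analysis of Boolean molecular networks.

Cells respond to extracellular stimuli through intracellular signaling
networks; this stimulus–response behavior is an input–output (IO)
relationship, and disease mutations — nodes locked ON (gain of function,
GOF) or OFF (loss of function, LOF) — can distort it. `bnrevert` asks
whether, and how, a distorted IO relationship can be *restored* by fixing
the states of a small set of other nodes ("reverse control"), without
touching the mutated gene itself.

## The method

A Boolean network updates each node `x_i` synchronously by a logic rule
`f_i` over its regulators. Input nodes (no regulators) model sustained
stimuli and hold their value; output nodes (no downstream targets) model
phenotypic readouts. Instead of enumerating attractors (NP-hard), the
package works on the **expanded network**: two literal nodes per gene
(ON/OFF) plus composite AND nodes built from the complete prime-implicant
sets (Blake canonical form) of each rule and its complement. The
**logical domain of influence (LDOI)** of a set of fixed node states —
a modified breadth-first closure on this graph — is a sufficient set of
stabilized node states.

For every input profile `I ∈ {0,1}^l` the inferred output is

```
Ô_j = 1   if  O_j=1 ∈ LDOI(I),
      0   if  O_j=0 ∈ LDOI(I),
      0.5 otherwise (undetermined by canalization),
```

and the map `M : I ↦ Ô` is the **IO matching**. A mutation is *effective*
when it changes `M`; a *reverse control* is a set of node fixations that
restores the wild-type `M` exactly. Internal nodes are classified:

* **C0** — both GOF and LOF ineffective;
* **C1** — exactly one effective (fixing the node at its ineffective
  value restores the matching: self-reversible);
* **C2** — both effective, every effective mutation reversible via
  downstream C1 fixations and/or overriding the node;
* **C3** — not reverse-controllable within the search budget.

Network-level measures: reversibility `V = 1 − N_C3/N_internal`;
redundancy `D = N_sp/N_p` (simple IO paths shorter than twice the
shortest path, per matched input-state/output instance); robustness to
mutation `B_m = Σ_k |A_o ∩ A_k| / (|A_o|·2N)` over all `2N` single-node
fixations (primary = largest sampled basin); robustness to perturbation
`B_p`, the fraction of (initial state, single-bit flip) pairs converging
to the same attractor. A degree-preserving configuration model with
random canalizing rules (one canalizing regulator forces the output on
half the truth table; the rest is an unbiased random function) supports
an ensemble study correlating `V` with `D`, `B_m` and `B_p`.

## Worked example

The packaged `fig1` fixture is a 7-node network (input `I`, output `O`,
internals A–E) with `O = (E | C) & C`:

```sh
$ bnrevert io fixtures:fig1
profile(I)  O
0           0
1           1
```

The stimulus fully determines the response: a deterministic IO matching.
Classifying the internal nodes:

```sh
$ bnrevert classify fixtures:fig1
node,class,gof_effective,lof_effective,gof_controls,lof_controls
A,C1,False,True,,
B,C2,True,True,"{B:=0, D:=1}",{D:=1}
C,C3,True,True,,
D,C1,False,True,,
E,C0,False,False,,
class ratios: C0: 1/5 (0.200)  C1: 2/5 (0.400)  C2: 1/5 (0.200)  C3: 1/5 (0.200)
```

GOF on A is harmless but LOF on A breaks the matching (so A is C1 and
fixing A=1 repairs it); both mutations of B are effective yet reversible
— LOF B by controlling `D:=1`, GOF B by `{B:=0, D:=1}` — so B is C2;
C is irreversible (C3, the output reduces to C alone); E never matters
(C0). Reversibility is `V = 1 − 1/5 = 0.8`:

```sh
$ bnrevert measures fixtures:fig1 --seed 7 --samples 1024
{
  "V": 0.8, "N_T": 1, "n_internal": 5,
  "D": 5.0, "N_sp": 10, "N_p": 2,
  "B_m": 0.5, "B_p": 0.857...,
  "n_samples": 1024, "seed": 7
}
```

Ten simple IO paths serve two matched instances (`D = 5`): plenty of
redundant routes from stimulus to response, which is exactly what makes
the network reversible.

The same workflow applies to published models supplied as `.bnet` files
(e.g. a bladder-cancer MAPK model placed under `models/`), including
mapping cell-line alteration profiles (packaged `table2_profiles`
fixture) onto network mutations via the gene-annotation table
(`table1_annotations`) and searching multi-mutation reversion targets
with `bnrevert revert`.

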