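# ssefold

RNA 3D structure prediction from sequence and secondary structure by
template assembly of smallest secondary elements (SSEs), with
restraint-guided simulated-annealing refinement and RMSD clustering.

Noncoding RNAs fold into tertiary structures that determine their
function, but solved structures lag far behind known sequences.
`ssefold` is for structural bioinformaticians who have a sequence and a
secondary structure (dot-bracket, pseudoknots allowed) and want
plausible all-atom 3D models: it decomposes the secondary structure into
a tree of SSEs (stems, hairpin/bulge/internal/junction loops), selects a
3D template for each node from an indexed library (or generates one de
novo by a bi-residue fragment method or distance geometry), assembles
the templates by Kabsch superposition over shared closing base pairs,
and refines the result by simulated-annealing Monte Carlo (SAMC) over
*movable elements* — contiguous spans whose rigid motion cannot break
any helix, so the secondary structure is preserved throughout.

Pseudoknots get a special treatment: instead of searching for (usually
missing) pseudoknot templates, the crossing base pairs are converted to
flat-bottom distance restraints and the refinement pulls the crossing
stem together.  Ensembles are clustered by k-means on the pairwise RMSD
matrix with the medoid rule

    s_i = argmin_k  Σ_{j≠k, j∈cluster i} d_{k,j}

and cluster representatives are ranked by a knowledge-based scoring
function (distance- and torsion-binned pseudo-energies).

Everything runs self-contained: an idealized A-form nucleotide geometry
(derived once, frozen in the package) powers a synthetic fixture
generator, so the full pipeline and its tests need no downloads.  For
real predictions, harvest a template library from experimental PDB
files with `ssefold library build`.

## Worked example

Predict a 22-nt pseudoknotted RNA.  The structure has a 5-bp stem and a
crossing 3-bp stem written in square brackets; the optimization task
converts those three pairs to restraints automatically:

```sh
ssefold optimize \
    --sequence CGUUAACAUUUAACGUCCUAAU \
    --structure "(((((..[[[)))))....]]]" \
    -n 1 --seed 1 --out out/
```

```
INFO ssefold.tasks: converted 3 pseudoknot pairs to restraints
INFO ssefold.optimizer: samc: 500 steps, acceptance 0.564, best energy 196.2761
wrote 1 models to out/
```

`out/` now holds `task_model1.pdb` plus a JSON manifest recording, per
model, the template provenance of every SSE, the SAMC seed and
acceptance ratio, the knowledge-based score (here 210.6, lower is
better), and the final violation of every restraint — here
`[0.031, 0.007, 0.004]` Å: all three pseudoknot pairs closed to within
a few hundredths of an Å of their canonical distance windows.  Compare
any model against a reference with:

```sh
ssefold eval --pred out/task_model1.pdb --native reference.pdb
```

which reports the all-atom superposed RMSD and the interaction network
fidelity INF = sqrt(PPV × STY) of canonical Watson-Crick pairs and of
helical stacking, each in [0, 1] (1 = the model reproduces the reference
interaction network exactly).

Other entry points: `ssefold assemble` (fast, assembly only),
`ssefold sample` (assembly + template-swap sampling + clustering),
`ssefold refine-only` (SAMC on an uploaded PDB model), `ssefold batch`
(one sequence with many structures, or paired sequence/structure
lists), `ssefold library build`, and `ssefold loopgen` for standalone
de novo loop generation.  The same functionality is available as a
library (`ssefold.tasks.run_task`, and the modules underneath).

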