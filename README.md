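# solnmr

Analysis pipeline for solution-NMR characterization of a protein: backbone
¹⁵N relaxation (T1, T2, heteronuclear NOE), rotational-correlation-time
estimation and oligomeric-state assessment, weighted chemical-shift
perturbation (CSP) mapping of ligand titrations, conformer-ensemble
precision statistics, and NOE distance-restraint bookkeeping. A
synthetic-data module generates every input with known ground truth, so the
whole pipeline is testable without any spectrometer data.

It is aimed at structural biologists who have per-residue peak lists
(relaxation decays, assigned amide shifts), a multi-model PDB ensemble and a
CYANA-style upper-limit restraint list, and want the standard per-residue
dynamics/perturbation/precision numbers with honest uncertainties.

## The quantities computed

**Relaxation.** Peak heights *I(t)* across relaxation delays *t* are fit per
residue by unweighted least squares to a single exponential
*I(t) = A·exp(−t/T)*; reported uncertainties are the square roots of the
covariance diagonal at the optimum. The steady-state heteronuclear NOE is
the ratio of peak heights with/without proton saturation,
NOE = I_sat/I_unsat, with the spectral signal-to-noise of both spectra
propagated into its error. The rotational correlation time follows from the
T1/T2 ratio:

    tau_c = 1/(4·pi·nu_N) · sqrt(6·(T1/T2) − 7)

with nu_N the ¹⁵N Larmor frequency (nu_N = 0.10132912·nu_H). Because tau_c
scales with molecular mass, comparing the mean tau_c against the window
expected for a monomer of the protein's mass gives an oligomeric-state
verdict.

**CSP.** For two assigned states (e.g. apo vs ligand-bound endpoint, the
right comparison in slow exchange) the weighted per-residue perturbation is

    CSP = sqrt(0.5·(ddH² + (0.2·ddN)²))   [ppm]

classified either against a fixed cutoff or against an iteratively trimmed
mean + 1 SD. CSPs can be written into a PDB B-factor column for structure
coloring, with −1.0 marking residues that have no data in one of the states.

**Ensemble precision.** Conformers are superposed by the Kabsch algorithm
(proper rotation enforced) onto an iteratively refined mean structure; the
package reports the mean ± SD over models of each model's rmsd to the mean
over a residue/atom selection, plus a per-residue rmsd profile that
localizes flexible segments.

**Restraints.** Upper-limit distance restraints are binned by sequence
separation s = |i−j| (intra s=0, sequential s=1, medium 1<s≤5, long s>5)
and summarized as totals and per-residue averages.

## Worked example

Generate a full synthetic data set for a 196-residue protein (T1 = 750 ms,
T2 = 70 ms, NOE 0.80 with flexible segments 8–20 and 133–153 at 0.40, 2%
peak-height noise, a 20-conformer ensemble, 3246 restraints) and analyze it:

```
$ solnmr simulate all --seed 1 --n-residues 196 --outdir demo/fixtures

$ solnmr relax fit --t1 demo/fixtures/t1.tsv --t2 demo/fixtures/t2.tsv \
    --noe demo/fixtures/noe.tsv --field-mhz 600 --tau-window 8:12 \
    --out demo/relax.tsv
mean T1 748.8 ms, mean T2 70.0 ms, mean tau_c 9.90 +/- 0.24 ns
oligomeric state: monomer-consistent
flexible residues (NOE < 0.65): 8,9,10,...,153

$ solnmr constraints summarize --upl demo/fixtures/constraints.upl \
    --phi 110 --psi 110 --n-residues 196 --out demo/table.tsv
3246 distance restraints (17.7/residue total, 4.2/residue long-range)

$ solnmr ensemble stats --pdb demo/fixtures/ensemble.pdb --out demo/ens.tsv
20 models, rmsd to mean 0.68 +/- 0.02 A over 2-7,21-135,148-195 (backbone_heavy)
```

Reading the numbers: the fitted means recover the injected ground truth
(750/70 ms) within noise; a mean tau_c of 9.9 ns lies inside the 8–12 ns
window supplied for a ~23 kDa monomer, hence the verdict; every residue of
the injected flexible segments is flagged by its low NOE; 824 long-range
restraints over 196 residues give the 4.2 per-residue average; and the
ensemble rmsd to the mean reflects the per-residue spread the generator
injected, elevated in the flexible segments (see `demo/ens.tsv` for the
profile).

`solnmr run-all --config config.yaml` runs every stage from one flat YAML
config and writes per-stage TSVs, a combined `report.txt` and a versioned
`summary.json`; command-line flags override config values.

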