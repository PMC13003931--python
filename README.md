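# psiquant

Quantification of targeted RNA pseudouridylation (Ψ) from amplicon
sequencing, with the supporting statistics used alongside such assays in
RNA base-editing studies.

Pseudouridine is chemically silent in ordinary sequencing. After CMC or
bisulfite (BID-seq) treatment, reverse transcription leaves a 1-nt
**deletion** in the cDNA at each modified position, so the deletion rate at
a site is a proxy for Ψ stoichiometry θ — but a biased one, because the
chemistry converts only a fraction of modified molecules. `psiquant`
implements the calibrated estimator

```
effective_psi = deletion_rate(sample) / deletion_rate(100% ΨTP standard)
```

where the standard is an in-vitro transcript of the same sequence context
with ΨTP fully substituting UTP, processed through identical chemistry.

The package provides:

* **CMC amplicon pipeline** (`psiquant.cmc`) — UMI collapse keeping the
  first occurrence of each 10-mer UMI, perfect 8-mer anchor matching around
  the target NΨN window, deletion-rate (gap 2) and mutation-rate (gap 3,
  non-T middle) computation, and standard normalization.
* **BID-seq pipeline** (`psiquant.bidseq`) — per-position deletion-rate
  pileups from covering-read records and site-level effective Ψ with the
  same normalization contract.
* **Assay statistics** (`psiquant.assays`) — ΔCq relative expression and
  nuclear/cytosolic enrichment ratios, molar-adjusted gel PSI, Sanger A>I
  editing fractions g/(a+g), luciferase FLuc/RLuc ratios, and the Pearson
  correlation of editing-performance ratios against gene covariates.
* **Synthetic-data generators** (`psiquant.simulate`) — seeded, bit-reproducible
  simulators for all of the above with per-molecule ground truth, including
  ΨTP standards, PCR duplicates sharing UMIs, and sequencing error.
* **CLI** (`psiquant`) — `simulate`, `cmc-quant`, `bidseq-quant`,
  `qpcr-ratio`, `gel-psi`, `sanger-edit`, `perf-corr`, `demo`,
  `validate-targets`.

See `docs/methods.md` for the model, assumptions and design choices.

## Worked example

Simulate a locus with true stoichiometry θ = 0.6 (10,000 molecules, 80 %
deletion conversion, 1 % background deletion, 0.5 % sequencing error, mean
2 PCR duplicates per molecule), plus a matched 100 % ΨTP standard, and
quantify:

```python
import dataclasses
import psiquant as pq
from psiquant.config import default_demo_target

target = default_demo_target()
params = pq.CmcSimParams(psi_fraction=0.6, p_del_psi=0.8, p_del_u=0.01,
                         seq_error=0.005, n_molecules=10_000, dup_mean=2.0,
                         seed=42)
reads, truth = pq.simulate_cmc_reads(target, params)
standard, _ = pq.simulate_standard(
    target, dataclasses.replace(params, seed=43), "psi100")
result = pq.quantify_reads(reads, standard, target)
```

which prints (via the fields of `result`):

```
input reads          19927
after UMI collapse   10655
anchor-matched       9768
deletion rate        0.4850
mutation rate        0.0026
standard deletion    0.8037
effective psi        0.6034
```

Reading the numbers: 19,927 sequenced reads collapse to ~10,000 molecules
(a few hundred phantom UMIs arise from sequencing errors inside the UMI);
~9 % of collapsed reads lose an anchor to sequencing error and drop out.
The raw deletion rate 0.485 ≈ θ·p_del_psi + (1−θ)·p_del_u underestimates
θ, and dividing by the standard's rate 0.804 recovers
effective Ψ = 0.603, within sampling error of the true 0.6 (the residual
+0.006 reflects the (1−θ)·p_del_u/p_del_psi background bias, here 0.005).

The same from the shell, end to end over a θ grid:

```sh
psiquant demo --seed 1 --outdir demo_out   # writes recovery.tsv + provenance.json
```

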