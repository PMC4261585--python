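# phylorates

Maximum-likelihood estimation of evolutionary rates of discrete characters
(any number of states) on a fixed phylogeny with branch lengths.

Features:

- **Transition models**: equal-rates (`ER`), symmetric (`SYM`),
  all-rates-different (`ARD`), general time-reversible (`GTR` = `SYM` +
  forced reversibility + estimated root prior), birth-and-death ladders with
  transitions only between neighbouring copy-number states (`BDER`, `BDSYM`,
  `BDISYM`, `BDARD`), and custom templates (a JSON grid tying off-diagonal
  cells to shared parameters; 0 = structural zero).
- **Calibration**: every generator is rescaled so the expected number of
  transitions per site per time unit is 1, making the rate `mu` directly
  interpretable.
- **Discrete-gamma rate variation** among sites (equal-probability
  categories with conditional-mean rates, mean exactly 1).
- **Estimable root priors** and **forced reversibility** (off-diagonal
  entries multiplied by destination-state probabilities, which enforces
  detailed balance). Irreversible analyses of unrooted trees are
  midpoint-rooted first.
- **Correction for unobservable data**: condition the likelihood on a site
  pattern being observable by dividing by `1 - L_minus`, the likelihood of
  the all-absent pattern (for systems such as gene families where anciently
  lost genes are invisible).
- **Branch-specific rates** via a `$k` Newick dialect (`(A$1:0.1,B$2:0.2);`
  assigns the branch above each labelled node to rate category `k`) and
  **per-site rates** with an optional plot.
- **Forward simulator** for parameter-recovery studies, with optional
  conditioning on observable patterns.

## CLI

```bash
# joint fit (binary collapse + unobservable-data correction)
phylorates fit --tree B1.tre --matrix B1_pattern --orientation taxa-in-columns \
    --model ER --simplify --zerocorrection --out-dir out/

# GTR is shorthand for SYM + --reversible + --rootprobability
phylorates fit --tree tree.nwk --matrix m.tsv --model GTR --out-dir out/

# two-rate (external vs internal branch) fit using a $-labelled tree
phylorates fit --tree B1_2rates.tre --matrix B1_pattern \
    --orientation taxa-in-columns --out-dir out2/

# likelihood-ratio test between two nested fit reports
phylorates lrt --report0 out/report.json --report1 out2/report.json

# per-site rates with a plot
phylorates fit-sites --tree yeast.tre --matrix intron_pattern \
    --orientation taxa-in-columns --plot rates.png --out-dir sites/

# simulate a matrix
phylorates simulate --tree tree.nwk --model ER --mu 1.5 --n-sites 1000 \
    --seed 7 --out-dir sim/
```

Character matrices are plain-text delimited integer tables; use
`--orientation` to declare whether taxa are rows or columns. Fits write a
deterministic `report.json` (and `per_site_mu.tsv` for `fit-sites`).

## Library

```python
import phylorates as pr

tree = pr.parse_newick(open("tree.nwk").read())
matrix = pr.read_character_matrix("matrix.tsv", "taxa_in_rows")
result = pr.fit(tree, matrix, "ER", zerocorrection=True)
print(result.mu, result.loglik)
```

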