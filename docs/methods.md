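# Methods

## Model and assumptions

A ME-model couples two layers. The metabolic layer is an ordinary
stoichiometric network at steady state, S·v = 0 with flux bounds, in
mmol gDW⁻¹ hr⁻¹. The expression layer adds the synthesis of every piece of
machinery — RNAs, proteins, processed proteins, complexes — and ties the
two layers together with growth-rate-dependent coupling coefficients.

The couplings all derive from dilution: at specific growth rate μ (hr⁻¹) a
macromolecule pool is passed to daughter cells at rate μ·[pool], so a
catalyst with effective turnover k_eff (s⁻¹) is consumed at
μ/(k_eff·3600) per unit of catalyzed flux. For templated polymerization the
per-template turnover is rate/length, giving machine usage μ·L/(rate·3600):
RNA polymerase usage scales with transcription-unit length (default
55 nt s⁻¹), ribosome usage with protein length (default 12 aa s⁻¹). These
defaults, the fallback enzyme k_eff of 65 s⁻¹ and the mRNA decay constant
k_deg = ln 2 / 0.083 hr⁻¹ (≈5 min half-life) are conventions of the field
for a fast-growing bacterium and are configurable per model
(`GlobalParameters`) and per reaction (`keff` attributes, keff table).

Every coefficient is restricted to the linear form `constant + slope·μ`
(`GrowthExpression`). This covers all couplings implemented here, makes
LP substitution exact, and is why no symbolic-algebra engine is needed.
Richer (e.g. hyperbolic) forms would require only a change of this one
class, since reactions manipulate coefficients exclusively through its
algebra.

### mRNA handling

Translation consumes mRNA at (μ + k_deg)/k_transl_eff with
k_transl_eff = ribosome_rate·3600/L_aa (hr⁻¹). The degraded fraction
k_deg/(μ+k_deg) returns its nucleotides exactly: one NMP per residue, one
water consumed per phosphodiester bond, plus 0.25 ATP→ADP+Pi per
nucleotide through the `mRNA_degradation` subreaction (with its
degradosome enzyme coupling when configured). The diluted fraction is lost
to daughter cells, which is precisely the μ-proportional part. The RNA
biomass tally is debited by the degraded mass so degraded mRNA never
counts as retained biomass.

### tRNA cycling and stable RNA

Charging consumes the uncharged tRNA at (1 + μ/(k_eff·3600)): the unit is
the charge/discharge cycle, the μ term is the dilution of the stable tRNA
pool that forces ongoing tRNA transcription in a growing cell. Elongation
subreactions return the uncharged tRNA 1:1 and spend 2 GTP per residue
(EF-Tu- and EF-G-like factors), with one GTP each for initiation and
termination; all of it is SubreactionData, i.e. data rather than code.

Stable-RNA operons are transcribed as one unit; mature products are
excised with one machinery usage per cut (a declared choice — the cost
apportionment for multi-RNA units is not standardized), and spacer
nucleotides return to the NMP pool at one water per freed residue. Every
RNA species also has a turnover valve returning it to NMPs. Without such
valves, RNAs co-produced on one operon (an rRNA and tRNAs) would be forced
into identical net demand, overdetermining the steady-state balances and
blocking all expression; with them, surplus transcript is degraded, as it
is in cells. Turnover is uncatalyzed and debits the RNA biomass tally, so
it is never profitable — just a relief valve.

### Chemistry conventions

All small molecules use neutral formulas. Macromolecule compositions are
residue sums: RNA = Σ NMP − N·H₂O (so N NTP → RNA + N PPi balances
exactly), protein = Σ AA − (L−1)·H₂O, complexes = Σ subunits plus the net
elemental flow of their modification subreactions (e.g. `mod_mg2` adds one
Mg). With these conventions every compiled non-exchange, non-summary
reaction balances C/H/N/O/P/S exactly at μ = 0, and the only imbalance at
μ > 0 is the elemental drain of diluted macromolecules — both properties
are enforced by `memodel.balance` and the test suite.

### Growth demand and the dummy protein

Growth is imposed by `biomass_dilution` (both bounds = μ) consuming a
biomass pool fed exclusively by *forced*, μ-scaled demands: the
dummy-protein demand plus fixed DNA and lipid demands (defaults 0.03 and
0.09 g gDW⁻¹ per unit μ, in the spirit of fixed biomass-function
coefficients rather than growth-dependent surface-area terms). The dummy
protein — default 100 residues, uniform over the 20 amino acids, gene
synthesized by round-robin codon choice — is also the catalyst assigned to
orphan reactions, so they carry a realistic expression cost, and its
demand is the LP objective.

Machinery mass is tallied (protein/RNA gram pools) but deliberately kept
out of the growth requirement, draining instead to reporting sinks. If
machinery mass counted toward an exactly-filled biomass total, making
*more* enzyme could substitute for dummy mass and a *lower* k_eff could
raise μ\* whenever the enzyme had a higher mass-per-carbon than the dummy.
With the demand-only biomass pool, every coupling is a pure burden: any
flux vector feasible under a smaller dilution coefficient remains
constructible under a larger k_eff by scaling the expression chain down
(all expression reactions have zero lower bounds), so μ\* is provably
non-increasing as any k_eff decreases. This is the monotonicity the tests
assert.

## Optimization

The ME-matrix is quasi-convex in μ: feasibility at μ implies feasibility
at every smaller μ. `bisect_max_growth` exploits this, solving one LP per
probe (default bracket [0, 2] hr⁻¹, tolerance 1e-12; double precision
limits anything much finer). The returned μ\* is always the last *feasible*
probe — a lower bound — with the infeasible bracket within one tolerance.
The same procedure serves batch and nutrient-limited growth because the
objective (dummy demand) is maximized in either case.

ME LPs are ill-scaled: coupling coefficients of order 1e-6 share rows with
biomass coefficients of order 10. Rather than an extended-precision
backend, the solver (scipy/HiGHS behind a minimal backend contract)

* row-equilibrates the constraint matrix (exact, since the right-hand side
  is zero),
* runs with 1e-9 primal/dual feasibility tolerances so per-row violation
  budgets stay far below the smallest couplings,
* verifies ‖S·v‖∞ after every solve, retrying once with tightened
  tolerances and rejecting solutions above 1e-6,
* treats probes that persistently fail numerically as infeasible (logged)
  — a conservative bias on μ\*.

FVA at fixed μ (`flux_variability_at_mu`) min/maximizes single columns,
optionally constraining the objective to a fraction of its optimum
(default 0: pure feasibility) and optionally flooring reported values at
1e-15, the log-plot convention. Near the growth boundary the subproblems
are inherently borderline; they fall back to presolve-off and, last, to a
relaxed primal tolerance.

Essentiality: knocking out a gene zeroes its translation reaction (and any
transcription unit whose sole product is that gene's RNA); the gene is
essential iff the model is infeasible at the threshold growth rate. By
quasi-convexity one feasibility probe decides this, so the screen costs
one LP per gene. The threshold has no default — it is an explicit
parameter everywhere, including the CLI.

### Explicit-constraint mode

`convert_to_explicit_constraints` rewrites every embedded dilution term
−s·μ on a macromolecule as: production of a coupling pseudo-metabolite at
+μ, plus a dilution arc consuming one pseudo-metabolite and s
macromolecules. The projected feasible set at every fixed μ is identical
by construction, while rows and columns grow strictly — the historical
formulation, kept as an equivalence oracle. The slope is placed on the arc
rather than the pseudo-metabolite row so both formulations present equally
conditioned rows to the solver.

## The toy organism

The generator emulates the full input stack — GenBank genome, COBRA-JSON
M-model, TU/enzyme/k_eff/translocation tables — for a deterministic
imaginary bacterium (byte-identical files per seed). Study conditions,
chosen once: 10 coding genes with fixed machinery roles (plus fillers), 20
tRNA genes and one rRNA gene, protein lengths 30–60 residues, glucose
uptake bound drawn once per seed from [6, 12] mmol gDW⁻¹ hr⁻¹,
per-reaction k_eff from [20, 150] s⁻¹, translocation k_eff from
[15, 40] s⁻¹. Lumped promiscuous enzymes (one amino-acid synthase complex,
one nucleotide synthase) keep the gene count small; currency-metabolite
balancing (glucose for C, ammonia for N, sulfide for S, phosphate for P,
water and H₂ absorbing O/H residuals) makes every synthesis reaction
elementally exact by construction. Growth is limited by carbon uptake and
machinery cost; μ\* lands around 0.8–1.5 hr⁻¹.

"Full" difficulty exercises every record type: a stable-RNA operon with
excision, an Mg-modified complex, an elongation-factor generic pool (two
paralogs sharing one composition by permutation), a Sec-translocated
membrane transporter, an orphan lipid synthesis, and one transcription
unit served by two sigma-factor holoenzymes. "Minimal" collapses to three
roles, no modifications/translocation/generics, and leaves most
transcription units to the builder's auto-generated single-gene fallback.

What the toy does **not** emulate: real kinetic parameters, energy
conservation (phosphorylation is carbon-costed but not
thermodynamically priced), RNA secondary structure or processing detail,
regulation, condition-dependent k_eff values, and realistic network
redundancy. Passing tests therefore demonstrate the correctness of the
framework's construction, coupling arithmetic and optimization — not
predictive accuracy on a real organism.

The growth-rate oracle is a pure linear grid scan (`brute_force_max_mu`),
sharing no code with bisection; `refined_max_mu` chains scans at steps
0.05 → 1e-3 → 2e-5 → 1e-6 so the 1e-6-resolution oracle costs a few
hundred LPs instead of two million. Problem sizes throughout the suite
(~130 metabolites × ~170 reactions, LPs in milliseconds) were chosen so
the full test suite and the acceptance script each complete in about a
minute on one core.

## Numerical choices and degenerate inputs

* Reversible metabolic reactions split into forward/reverse
  MetabolicReactions, one per catalyzing complex
  (`<id>_FWD_<complex>`/`_REV_`); spontaneous reactions carry no catalyst;
  orphans get the dummy complex.
* GTG/TTG starts translate as initiator Met; the start-codon set is
  configurable. Recoding (selenocysteine) is unsupported.
* Registry re-registration with identical content is idempotent; the same
  id with different content raises — silent overwrites would hide
  inconsistencies between input tables.
* Enzyme-table complexes win over GPR-derived gene sets; ambiguous matches
  are resolved deterministically (sorted) and logged; unmatched
  conjunctions get auto-generated complexes.
* Missing k_eff falls back to the global default; genes without a declared
  TU get an auto single-gene TU under the default polymerase.
* Bisection on an infeasible lower bracket raises immediately
  (`InfeasibleAtMinError`); an upper bracket below the true optimum
  returns the bracket itself, flagged feasible.
* Serialized models carry `schema_version`; readers reject newer majors
  and report malformed entries with JSON-pointer paths.

## Known limitations

* Coupling coefficients are strictly linear in μ; saturating ribosome
  efficiency would need a generalized coefficient class.
* Membrane surface-area (crowding) constraints are intentionally out of
  scope.
* The solver contract assumes an LP backend with ~1e-9 feasibility
  tolerance; exactly at the growth boundary verdicts are
  tolerance-limited, which is why equivalence checks compare optima at
  2× the bisection tolerance rather than exactly.
* The E. coli-scale reconstruction requires curated organism data not
  bundled here; the builder is organism-agnostic but only toy-scale inputs
  are generated in-repo.
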