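# Methods

## Problem and procedure

An HDSS registry is a longitudinal, household-based roster of residency
episodes: one row per dated interval of residence of one person in one
household, so a person who left and returned holds several record IDs.
Clinic attendees report identifiers verbally; spellings drift, names are
reported in different orders, married women may appear under a maiden
name, and birth dates are recalled imprecisely. `poclink` ranks registry
candidates for the patient at the desk so a fieldworker can resolve the
remaining ambiguity interactively — by checking household membership,
asking about earlier residences, and re-running the search with amended
details.

## Match score

For each field *i* with match probability m_i and chance-agreement
probability u_i, the pair weight is log2(m_i/u_i) on agreement and
log2((1−m_i)/(1−u_i)) on disagreement; the score is the sum over fields
under the usual conditional-independence assumption. A field missing on
either side contributes exactly 0: the model neither rewards nor
penalises what was not asked or not recorded. Every record in the
registry is scored (no blocking or indexing); a full scan is simple,
exact, and fast enough at the intended registry scale (~10^5 rows, with
an LRU cache on the token comparator since name pools repeat heavily).
Ties in score are broken by record ID ascending so results are
deterministic.

### Agreement rules

- **Names** (up to 3): all pairwise Jaro–Winkler scores between reported
  and registry names are computed and the one-to-one assignment
  maximising the summed score is chosen (`scipy` Hungarian solver).
  Each paired name agrees at score ≥ 0.8; unpaired names are missing.
  The assignment — rather than a per-name maximum — makes the score
  invariant to name order and prevents one registry token from being
  credited twice. Whether the original fieldwork software aggregated by
  assignment or by per-name maximum is unknown; assignment is this
  package's documented choice.
- **Jaro–Winkler variant**: prefix scale 0.1, maximum common prefix 4,
  boost applied unconditionally (no Jaro pre-threshold) — the most
  common published variant.
- **Sex, village, sub-village**: exact equality after uppercasing and
  trimming. Village and sub-village are weighted as two separate
  fields.
- **Year of birth**: agreement iff |Δ| ≤ 2 years; month and day of birth
  require exact equality (the recall tolerance is stated for the year
  only).
- **Household-member and TCL name groups**: agree when any assigned name
  pair reaches the 0.8 threshold. These enter the score as fields with
  their own m/u rather than serving only manual review; that is a
  design choice, flagged as such.

### Parameters

m and u are configuration, not estimates from labelled matches (no EM).
Defaults, overridable in YAML (`poclink init-config`):

| field | m | fallback u |
|---|---|---|
| name1/2/3 | 0.90 | 0.01 |
| sex | 0.95 | 0.50 |
| birth year | 0.90 | 0.08 |
| birth month | 0.80 | 1/12 |
| birth day | 0.70 | 1/31 |
| village / sub-village | 0.90 | 0.10 / 0.02 |
| hh-member / TCL names | 0.80 | 0.02 / 0.05 |

The m values express that names and years are reported reliably but not
perfectly, with day of birth the weakest field. The fallback u values
are plausible chance-agreement rates for the setting (≈50/50 sex split,
birth years spread over decades against a ±2-year window, a handful of
villages); they only matter until `MatchParameters.with_estimated_u`
replaces them with the registry's own chance-agreement rates — the
probability that two distinct random records agree under each field's
rule, computed in closed form for exact-match fields
(Σ f_c(f_c−1)/n(n−1)) and by exhaustive or sampled pair enumeration for
tolerance/threshold fields. Estimates are clamped to (1e-6, 1−1e-6) so
weights stay finite on degenerate (near-constant) fields.

### Warnings

Before a match is assigned the reviewer is warned when |Δ birth year| >
10, or when the summed best-assignment score of the *patient* names is
≤ 1.6 (boundary inclusive). The sum covers patient names only, not the
household/TCL groups — with at most three names the 1.6 bar is then
meaningful; this interpretation is documented rather than certain.

## Identifiers, sessions, store

HTC numbers validate under ISO 7064 MOD 97-10 (N mod 97 == 1), the
convention both documented example IDs satisfy; on numbers of ≤ 8 digits
this catches every single-digit substitution. CTC and ANC formats
(`##-##-####-######`, `serial/year/FACILITY` with year 1990–2099) are
generalised minimally from single printed examples — the true grammars
are unknown. Whitespace is stripped before validation since printed
cards show stray spaces.

Rows are keyed by (machine name, session ID, record number): the session
ID is the local start time as YYYYMMDDHHMMSS, record numbers are
six-digit counters per session. A per-machine allocator bumps a session
starting in an already-used second to the next free second (also
consulting the store, so repeated invocations never collide).

The store is a single-file sqlite database with four tables (search
attempts, matches, notes, visits). End-of-day JSON backups merge by
primary key: identical rows collapse, conflicting payloads resolve to
the newest `created_at` with a deterministic payload tie-break, making
the merge idempotent and order-independent. Clinic IDs are linked
transitively across sessions (union-find), so a patient registered with
an ANC and an HTC number in one visit is retrievable by either later.
Optional at-rest encryption of the backup container uses a stdlib
construction (PBKDF2-HMAC-SHA256 key derivation, SHA-256 counter-mode
keystream, HMAC-SHA256 tag). It is obfuscation for field laptops, not a
vetted AEAD — no audited cryptography library is assumed present — and
it is off by default.

## QC flags

Patients (clinic-ID clusters) matched to ≥ 2 registry records are
checked pairwise: birth years > 10 years apart, conflicting sex, shared
household (legitimate duplicate episodes live in *different*
households), and overlapping residency episodes (strict interval
overlap; an open episode overlaps anything starting later; back-to-back
years do not overlap). Age uses birth year only. Flags are reported
for review, never auto-resolved — including the case of one clinic ID
apparently used by two people, which surfaces here rather than being
adjudicated.

## Synthetic data

The generator emulates the structure linkage has to cope with:
households of 1–8 co-residents, one TCL per block of ~10 households,
names drawn from invented Tanzanian-plausible pools, partial birth
dates, and a configurable fraction (default 10%) of identities holding
2–3 residency-episode records under distinct IDs in different
households. Query corruption applies, at configurable seeded rates,
single-character typos (substitution / adjacent transposition /
deletion — one edit each), name-order swaps, maiden-name substitution,
birth-year jitter, and field missingness; cohorts mix in a configurable
fraction of "recent residents" (default 25%) who have no true record at
all. Default rates (typo 0.3/name, swap 0.1, maiden 0.05, jitter ±1
year at 0.3) are chosen once as field-realistic; the original
corruption script's parameters are not published.

What the generator does **not** emulate: real name frequency skew and
ethnolinguistic structure, correlated field errors (a wrong card copied
twice), within-household name similarity, registry-side data entry
errors, or longitudinal household membership change. A green
rank-recovery test therefore shows the engine separates signal from
chance agreement under the stated corruption model — not field
performance on real data.

A packaged fixture (`table1_fixture`) is a synthetic stand-in
reconstructing the three documented worked cases (true record IDs,
reported identifiers, a spelling-perturbed registry spelling, switched
name order, a maiden-name episode) inside 100 records of generated
decoys; the original supplementary fake dataset is not redistributable,
so replay tests run against this stand-in.

## Numerical and design notes

- Scores are plain doubles; comparisons in tests use absolute
  tolerances of 1e-9–1e-12 where the value is analytic.
- `estimate_u` samples at most 100,000 pairs (seeded) above that pair
  count; below it, enumeration is exhaustive and exact.
- The CLI is a thin layer over the library: every interactive action
  maps to one library call, and a transcript of events is returned so
  the session can be audited against store contents.
- Known limitations: per-query search only (no global 1-to-1 batch
  assignment), no EM parameter estimation, single-writer store, no
  blocking (deliberate), and CTC/ANC format rules generalised from one
  example each.
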