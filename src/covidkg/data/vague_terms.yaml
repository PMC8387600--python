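# Default taxonomy of vague terms used by the vagueness scorer.
# Four categories: modal verbs, conditional terms, generalization terms,
# and generalizing numeric terms.  Multi-word entries are matched as
# phrases (longest match wins, matches never overlap).
modal_verbs:
  - may
  - might
  - can
  - could
  - would
  - likely
  - possible
  - possibly
conditional_terms:
  - depending
  - necessary
  - appropriate
  - inappropriate
  - as needed
  - as applicable
  - otherwise reasonably
  - sometimes
  - from time to time
generalization_terms:
  - generally
  - mostly
  - widely
  - general
  - commonly
  - usually
  - normally
  - typically
  - largely
  - often
  - primarily
  - among other things
generalizing_numeric_terms:
  - anyone
  - certain
  - everyone
  - numerous
  - some
  - most
  - few
  - much
  - many
  - various
  - including but not limited to
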