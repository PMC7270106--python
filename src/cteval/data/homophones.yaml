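# Small homophone / near-phone confusion list used by the synthetic
# error channel: a substituted word is drawn from its confusion set when
# one exists, emulating the sound-alike errors ASR systems make.
confusions:
  buy: [bye, by]
  bye: [buy, by]
  by: [buy, bye]
  ate: [eat, eight]
  eat: [ate]
  died: [dying, dyed]
  dying: [died]
  dead: [death, dad]
  death: [dead, deaf]
  hurt: [dirt, heart]
  dirt: [hurt]
  appeal: [kill, a-peel]
  kill: [appeal]
  depressed: [the-preston, pressed]
  hers: [hurts]
  his: [these, is]
  eating: [made, heating]
  two: [too, to]
  too: [two, to]
  there: [their]
  their: [there]
  know: [no]
  no: [know]
  here: [hear]
  hear: [here]
  right: [write]
  write: [right]
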