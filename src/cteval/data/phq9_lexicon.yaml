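# PHQ-9 keyword lexicon: for each item of the Patient Health
# Questionnaire, the clinically relevant keywords (UMLS-expanded list
# frozen as data).  Multiword keywords are space-separated and matched
# as token sequences.
categories:
  - id: 1
    label: anhedonia (little interest or pleasure)
    keywords: [interest, interested, interesting, interests, pleasure]
  - id: 2
    label: depressed mood
    keywords: [depressed, depressing, feeling down, hopeless, miserable]
  - id: 3
    label: sleep problems
    keywords: [asleep, drowsy, sleepiness, sleeping, sleepy]
  - id: 4
    label: fatigue / low energy
    keywords: [energy, tired]
  - id: 5
    label: appetite change (overeating)
    keywords: [overeat, overeating]
  - id: 6
    label: feeling bad about yourself
    keywords: [bad, badly, poorly]
  - id: 7
    label: trouble concentrating
    keywords: [mindfulness]
  - id: 8
    label: psychomotor change
    keywords: [fidget, fidgety, restless, slow, slowing, slowly]
  - id: 9
    label: suicidal or death-related ideation
    keywords: [dead, death, depression, died, suicide]
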