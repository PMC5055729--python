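# Default keyword groups: each entry maps a primary keyword to its aliases.
# Symptom groups cover common infectious-illness symptoms and conditions;
# emotion groups cover six basic emotions plus "happy" split into its own
# category (it behaves as a calendar-event signal, not generic joy).
symptom:
  headache: [head ache, migraine, migraines, headaches]
  vomit: [throwing up, being sick, vomiting, puke, puking, threw up, thrown up]
  hayfever: [hay fever, pollen allergy]
  sore throat: [throat hurts, scratchy throat, painful throat]
  pain: [aching, in agony, agonising]
  malaise: [run down, under the weather, feeling rough]
  flu: [influenza, the flu, flu like]
  cough: [coughing, coughs, hacking cough]
  tonsillitis: [tonsilitis, swollen tonsils]
  common cold: [a cold, head cold, caught a cold]
  infection: [infected, infections]
  abdominal pain: [stomach ache, tummy ache, stomach pain, belly ache]
  sneeze: [sneezing, sneezes, sneezed]
  asthma: [asthmatic, asthma attack, inhaler]
  shortness of breath: [short of breath, breathless, struggling to breathe]
  earache: [ear ache, ear infection, ear hurts]
  nasal congestion: [blocked nose, stuffy nose, bunged up]
  tremor: [tremors, shaking hands, the shakes]
  itch: [itchy, itching, itches, scratching]
  anxiety: [anxious, panic attack, panicky]
  fever: [feverish, high temperature, burning up]
  nosebleed: [nose bleed, bleeding nose]
  faint: [fainted, fainting, passed out]
  skin rash: [rash, rashes, come out in a rash]
  cramp: [cramps, cramping, stomach cramps]
  diarrhea: [diarrhoea, the runs, upset stomach]
  chest pain: [chest hurts, pain in my chest, tight chest]
  swollen gland: [swollen glands, glands are up]
  conjunctivitis: [pink eye, eye infection]
  stinging sensation: [stinging, stings, burning sensation]
  bleeding: [bleeds, blood loss]
  chickenpox: [chicken pox, the pox]
  runny nose: [nose is running, streaming nose, sniffles]
  swelling: [swollen, puffed up, puffy]
  meningitis: [meningococcal]
  pneumonia: [chest infection, lung infection]
  seizure: [seizures, fit, convulsions]
  constipation: [constipated, bunged up inside]
  palpitation: [palpitations, heart racing, racing heart]
  norovirus: [winter vomiting bug, stomach bug, sickness bug]
  neck pain: [stiff neck, neck hurts, sore neck]
  scarlet fever: [scarlatina]
  dehydration: [dehydrated, parched]
  dysentery: []
  tearing: [eyes watering, watery eyes]
  dry mouth: [mouth is dry, cotton mouth]
emotion:
  love: [loving, adore, adored, affection, fond of, in love]
  joy: [glad, delighted, pleased, joyful, cheerful, jolly, elated, enjoy, thrilled]
  happy: [happiness, happier, happiest]
  surprise: [amazed, astonished, surprised, astounded, amazement, astonishment, shocked, stunned]
  sadness: [depressed, unhappy, crying, sad, sorrow, grief, gloomy, miserable, heartbroken, tearful]
  anger: [angry, furious, rage, raging, annoyed, irritated, outraged, fuming, livid]
  fear: [afraid, scared, terrified, frightened, panic, worried, petrified, dread]
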