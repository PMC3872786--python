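{
  "version": "1.0",
  "note": "Basic-emotion term sets proposed by different emotion theorists. The 'variant_forms' set is a synthetic reconstruction: adjectival/derived surface forms of the listed terms (the published appendix enumerating all 78 surface forms is not reproduced here), included so that the union covers the full 78-term pool, among them the forms selected into the 8-term and full predictor models.",
  "sources": {
    "ekman_friesen_ellsworth": ["anger", "disgust", "fear", "happiness", "sadness", "surprise"],
    "ekman": ["amusement", "anger", "contempt", "contentment", "disgust", "embarrassment", "excitement", "fear", "guilt", "happiness", "interest", "pleasure", "pride", "relief", "sadness", "satisfaction", "shame", "surprise"],
    "kassam": ["anger", "disgust", "envy", "fear", "happiness", "lust", "sadness", "shame"],
    "osgood": ["active", "bad", "good", "passive", "strong", "weak"],
    "panksepp": ["care", "fear", "lust", "panic", "play", "rage", "seeking"],
    "plutchik": ["anger", "anticipation", "disgust", "fear", "joy", "sadness", "surprise"],
    "reizenzein": ["aversion", "desire", "disappointment", "fear", "happiness", "hope", "relief", "surprise", "unhappiness"],
    "robinson": ["approach", "arouse", "away", "danger", "evaluate", "from", "safe", "to", "toward", "withdraw"],
    "stevenson": ["anger", "disgust", "fear", "happiness", "sadness"],
    "tomkins_mild": ["anger", "contempt", "distress", "enjoyment", "fear", "interest", "shame", "surprise"],
    "tomkins_strong": ["anguish", "disgust", "excitement", "humiliation", "joy", "rage", "startle", "terror"],
    "wundt": ["depression", "excitement", "pleasant", "relaxation", "tension", "unpleasant"],
    "variant_forms": ["admirable", "amused", "angry", "ashamed", "content", "desirable", "disgusted", "envious", "excited", "fearful", "guilty", "happy", "hopeful", "horny", "interested", "proud", "relieved", "sad", "surprised"]
  },
  "eight_term_model": ["admirable", "arouse", "envious", "from", "good", "horny", "pleasure", "proud"],
  "full_model_terms": ["admirable", "arouse", "envious", "good", "horny", "pleasure", "proud"]
}
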