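# Item dictionary for the two-reporter behaviour questionnaire (25 items,
# five 5-item subscales, 3-point frequency scale) and the 6-item parent
# distress screen.  Reverse-flagged items are scored as (2 - value).
# reference_mean / reference_sd are published item-level statistics for
# 17-year-olds (scored metric, reverse applied); the synthetic generator
# uses them as default calibration targets.
scale:
  min: 0
  max: 2
subscales:
  conduct:
    items: [5, 7, 12, 18, 22]
    reverse: [7]
    parent:
      text:
        5: "Often has temper tantrums or hot tempers"
        7: "Generally obedient"
        12: "Often fights with other children"
        18: "Often lies or cheats"
        22: "Steals from home, school, or elsewhere"
      reference_mean: {5: 0.40, 7: 0.42, 12: 0.04, 18: 0.14, 22: 0.04}
      reference_sd: {5: 0.63, 7: 0.57, 12: 0.24, 18: 0.40, 22: 0.23}
    self:
      text:
        5: "I get very angry"
        7: "I usually do as I am told"
        12: "I fight a lot"
        18: "I am often accused of lying or cheating"
        22: "I take things that are not mine"
      reference_mean: {5: 0.53, 7: 0.65, 12: 0.15, 18: 0.19, 22: 0.11}
      reference_sd: {5: 0.65, 7: 0.56, 12: 0.40, 18: 0.46, 22: 0.35}
  hyperactivity:
    items: [2, 10, 15, 21, 25]
    reverse: [21, 25]
    parent:
      text:
        2: "Restless, overactive"
        10: "Constantly fidgeting or squirming"
        15: "Easily distracted, concentration wanders"
        21: "Thinks things out before acting"
        25: "Sees tasks through to the end"
      reference_mean: {2: 0.32, 10: 0.23, 15: 0.52, 21: 0.65, 25: 0.57}
      reference_sd: {2: 0.58, 10: 0.52, 15: 0.67, 21: 0.62, 25: 0.64}
    self:
      text:
        2: "I am restless"
        10: "I am constantly fidgeting"
        15: "I am easily distracted"
        21: "I think before I do things"
        25: "I finish the work I am doing"
      reference_mean: {2: 0.90, 10: 0.64, 15: 0.93, 21: 0.68, 25: 0.77}
      reference_sd: {2: 0.69, 10: 0.72, 15: 0.72, 21: 0.58, 25: 0.62}
  emotion:
    items: [3, 8, 13, 16, 24]
    reverse: []
    parent:
      text:
        3: "Often complains of headaches"
        8: "Many worries"
        13: "Often unhappy, downhearted"
        16: "Nervous or clingy in new situations"
        24: "Many fears, easily scared"
      reference_mean: {3: 0.39, 8: 0.55, 13: 0.27, 16: 0.45, 24: 0.29}
      reference_sd: {3: 0.63, 8: 0.68, 13: 0.55, 16: 0.65, 24: 0.55}
    self:
      text:
        3: "I get a lot of headaches"
        8: "I worry a lot"
        13: "I am often unhappy"
        16: "I am nervous in new situations"
        24: "I have many fears"
      reference_mean: {3: 0.45, 8: 1.07, 13: 0.47, 16: 1.05, 24: 0.49}
      reference_sd: {3: 0.65, 8: 0.77, 13: 0.65, 16: 0.76, 24: 0.66}
  peer:
    items: [6, 11, 14, 19, 23]
    reverse: [11, 14]
    parent:
      text:
        6: "Rather solitary, tends to play alone"
        11: "Has at least one good friend"
        14: "Generally liked by other children"
        19: "Picked on or bullied by other children"
        23: "Gets on better with adults than with other children"
      reference_mean: {6: 0.50, 11: 0.16, 14: 0.20, 19: 0.18, 23: 0.63}
      reference_sd: {6: 0.67, 11: 0.45, 14: 0.44, 19: 0.47, 23: 0.70}
    self:
      text:
        6: "I am usually on my own"
        11: "I have one good friend or more"
        14: "Other people my age generally like me"
        19: "Other children or young people pick on me"
        23: "I get on better with adults than with people my age"
      reference_mean: {6: 0.58, 11: 0.16, 14: 0.51, 19: 0.13, 23: 0.70}
      reference_sd: {6: 0.68, 11: 0.42, 14: 0.58, 19: 0.38, 23: 0.69}
  prosocial:
    items: [1, 4, 9, 17, 20]
    reverse: []
    parent:
      text:
        1: "Considerate of other people's feelings"
        4: "Shares readily with other children"
        9: "Helpful if someone is hurt"
        17: "Kind to younger children"
        20: "Often volunteers to help others"
      reference_mean: {1: 1.71, 4: 1.69, 9: 1.78, 17: 1.87, 20: 1.44}
      reference_sd: {1: 0.48, 4: 0.54, 9: 0.46, 17: 0.37, 20: 0.64}
    self:
      text:
        1: "I try to be nice to other people"
        4: "I usually share with others"
        9: "I am helpful if someone is hurt"
        17: "I am kind to younger children"
        20: "I often volunteer to help others"
      reference_mean: {1: 1.79, 4: 1.49, 9: 1.65, 17: 1.77, 20: 1.19}
      reference_sd: {1: 0.42, 4: 0.59, 9: 0.52, 17: 0.46, 20: 0.64}
distress:
  n_items: 6
  min: 0
  max: 4
  high_cutoff: 5
education:
  high_min_level: 4
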