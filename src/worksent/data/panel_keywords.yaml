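# Panel-elicited primary keyword categories.
# category1: nouns implying work, the office, or the workplace.
# category2: adjectives signifying sentiment (positive, negative, or neutral).
# category3: phrases that explicitly mean sentiment about work or the workplace.
category1:
  - work
  - job
  - industry
  - labor
  - office
  - workplace
  - occupation
  - employment
  - employee
  - employer
  - corporate
  - company
  - enterprise
  - profession
  - meet deadlines
  - cubicle
category2:
  - stress
  - anxiety
  - depression
  - inefficiency
  - multitasking
  - breaking point
  - overload
  - burnout
  - stressed out
  - under pressure
  - demoralization
  - depressed mood
  - horrific
  - shocking
  - dangerous
  - problematic
  - undesirable
  - sad
  - struggle
  - stressed
  - depressed
  - ill
  - illness
  - mental strain
  - best lucky
  - bepositive
  - bethet united
  - get in
  - vibes
  - ftw
  - accomplished
  - let's get it done
  - mic dropped alhamdulillah
  - agreed
  - happy
  - good
  - enjoyment
  - proud
  - satisfaction
  - bad
  - unlucky
  - sorry
  - worse
  - hurt
  - tiring
  - long-day
  - boring
  - exhausted
  - hopeful
  - 2ndhome
  - standwith
  - godspeed
  - more to follow
category3:
  - overwork
  - wage slave
  - ironwork
  - mental health
  - congratulations office
  - work life
  - workoholic
  - worklifebalance
  - job strain
  - bad day at the office
  - when going gets tough workaholic gets going
  - comeback
  - back to drawing board
  - work-life balance
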