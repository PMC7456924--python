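>LSU1
MQQQAEAAAARQRQQQQLQQQQAQLQAALQQAQQRAARAKAEKKKAAAAQEQLCQALQQLAAQQLQAQQQRQQAQAQLQQQAAALAQQARKEQKEEQKKE
>LSU2
MQAAQEEQQAAERAQAALQQAAQEQAQALQQQAQAQLAQAQAQKREQQQAEQLCQALAQLAQQQLQAAARAKAAQQALQQQLAALQQAAKKEQAKEQQQR
>LSU3
MQAAAQRRQRRAAQAQQLQAAQQALQAQLAAAARRARREKKQKARQAQQAEQLCQALQQLAAAQLAQQQEAKRQAQALAAQQAQLQAAAEREEAAQERKR
>LSU4
MQQQAKKEKKKRRQQQQLAAQAKAQQAQLAAQQAQQLQAQQAAAEAAAQQEALCQQLQQLQAAQLAAAAKKEKAQQQLAAQLAQQQRAKQEKRQEAAERE
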