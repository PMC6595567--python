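<?xml version='1.0' encoding='UTF-8'?>
<!-- Demonstrates opaque retention: the EXCLUDED_STUDIES table and the
     MAIN_TEXT block are outside the supported subset; rm5kit keeps them
     verbatim and re-emits them in document order on write. -->
<COCHRANE_REVIEW ID="EX-RETAINED" REVMAN_VERSION="5.3">
  <COVER_SHEET><TITLE>Olanzapine versus placebo for schizophrenia</TITLE></COVER_SHEET>
  <STUDIES_AND_REFERENCES>
    <STUDIES>
      <INCLUDED_STUDIES>
        <STUDY ID="Chen 2005">
          <REFERENCE ID="EX-RETAINED-01-1"><TI>Olanzapine RCT</TI><YR>2005</YR></REFERENCE>
        </STUDY>
        <STUDY ID="Garcia 2010">
          <REFERENCE ID="EX-RETAINED-02-1"><TI>Olanzapine maintenance study</TI><YR>2010</YR></REFERENCE>
        </STUDY>
      </INCLUDED_STUDIES>
      <!-- not parsed into the model; retained opaquely -->
      <EXCLUDED_STUDIES>
        <STUDY ID="Excluded 1990"><REFERENCE ID="x1"><TI>Not randomised</TI></REFERENCE></STUDY>
      </EXCLUDED_STUDIES>
    </STUDIES>
  </STUDIES_AND_REFERENCES>
  <CHARACTERISTICS_OF_STUDIES>
    <CHARACTERISTICS_OF_INCLUDED_STUDIES>
      <INCLUDED_CHAR STUDY_ID="Chen 2005">
        <CHAR_METHODS><P>Allocation: randomly allocated. Blinding: open label. Duration: 8 weeks.</P></CHAR_METHODS>
        <CHAR_PARTICIPANTS><P>N=64 outpatients with schizophrenia.</P></CHAR_PARTICIPANTS>
      </INCLUDED_CHAR>
    </CHARACTERISTICS_OF_INCLUDED_STUDIES>
  </CHARACTERISTICS_OF_STUDIES>
  <RISK_OF_BIAS/>
  <ANALYSES_AND_DATA>
    <COMPARISON ID="CMP-01">
      <CONT_OUTCOME ID="OUT-01.01">
        <NAME>Average endpoint score (BPRS)</NAME>
        <CONT_DATA STUDY_ID="Chen 2005" MEAN_1="32.5" SD_1="8.1" TOTAL_1="32" MEAN_2="38.2" SD_2="9.4" TOTAL_2="32"/>
        <CONT_DATA STUDY_ID="Garcia 2010" MEAN_1="30.1" SD_1="7.2" TOTAL_1="45" MEAN_2="36.0" SD_2="8.8" TOTAL_2="44"/>
      </CONT_OUTCOME>
    </COMPARISON>
  </ANALYSES_AND_DATA>
  <!-- review prose: outside the subset, retained opaquely -->
  <MAIN_TEXT><SUMMARY><P>Plain language summary.</P></SUMMARY></MAIN_TEXT>
</COCHRANE_REVIEW>
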